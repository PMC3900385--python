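"""ATP accounting from K⁺ flux and bits-per-ATP efficiency.

The Na⁺/K⁺ pump imports 2 K⁺ per ATP hydrolysed, so the energy cost of
a voltage response is the total K⁺ charge moved across the membrane
divided by twice the elementary charge.  The K⁺ current is the
delayed-rectifier current plus the K⁺-permeable branch of the leak,
obtained by splitting the leak conductance into K⁺- and Na⁺-permeable
branches that jointly reproduce the original leak I–V curve exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from numba import njit

from . import biophysics
from .biophysics import BiophysParams
from .simulate import SimulationResult, VoltageTrace

ELEMENTARY_CHARGE = 1.602176634e-19   # C
FARADAY = 96485.33212                 # C/mol
AVOGADRO = 6.02214076e23              # 1/mol
UM2_TO_CM2 = 1e-8


@dataclass
class EnergyReport:
    k_charge: float            # C (signed, outward positive)
    atp_per_second: float
    info_rate: Optional[float] = None   # bits/s
    efficiency: Optional[float] = None  # bits/ATP

    def with_info(self, info_rate: float) -> "EnergyReport":
        return EnergyReport(self.k_charge, self.atp_per_second, info_rate,
                            efficiency(info_rate, self.atp_per_second))


def split_leak(g_leak: float, e_leak: float, e_k: float, e_na: float
               ) -> tuple[float, float]:
    """Unique (g_leak_K, g_leak_Na) with g_K + g_Na = g_leak and a joint
    reversal at E_leak, so the two branches reproduce the leak current at
    every potential."""
    if not (e_k < e_leak < e_na):
        raise ValueError("E_leak must lie between E_K and E_Na")
    g_k = g_leak * (e_na - e_leak) / (e_na - e_k)
    return g_k, g_leak - g_k


def total_k_current(result: SimulationResult) -> np.ndarray:
    """Delayed-rectifier plus K⁺-permeable leak current (µA/cm², outward
    positive)."""
    p = result.config.params
    g_lk, _ = split_leak(p.g_leak, p.e_leak, p.e_k, p.e_na)
    return result.current_k() + g_lk * (result.voltage.values - p.e_k)


def atp_consumption(k_current: np.ndarray, area: float, duration: float,
                    dt: Optional[float] = None,
                    mode: Literal["signed", "rectified"] = "signed") -> float:
    """ATP molecules/s pumped to clear the K⁺ flux of ``k_current``.

    ``k_current`` in µA/cm² (outward positive), ``area`` in µm².  The
    signed mode integrates the current as-is (inward K⁺ at V < E_K
    reduces pump load); rectified counts outward flux only.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    i = np.asarray(k_current, float)
    if mode == "rectified":
        i = np.clip(i, 0.0, None)
    if dt is None:
        dt = duration / i.size
    # µA/cm² × cm² × s → µC → C
    charge = float(i.sum()) * dt * area * UM2_TO_CM2 * 1e-6
    ions = charge / ELEMENTARY_CHARGE          # = charge · N_A / F
    return ions / 2.0 / duration


def energy_report(result: SimulationResult,
                  mode: Literal["signed", "rectified"] = "signed") -> EnergyReport:
    ik = total_k_current(result)
    duration = result.voltage.duration
    p = result.config.params
    atp = atp_consumption(ik, p.area, duration, result.dt, mode)
    charge = float(ik.sum()) * result.dt * p.area * UM2_TO_CM2 * 1e-6
    return EnergyReport(charge, atp)


def efficiency(info_rate: float, atp_rate: float) -> float:
    """bits per ATP molecule."""
    if atp_rate <= 0:
        raise ValueError("atp_rate must be positive")
    return info_rate / atp_rate


@njit(cache=True)
def _det_n_current(v, dt_ms, n0, g_k, e_k):
    """Deterministic delayed-rectifier current along a voltage path."""
    out = np.empty(v.size)
    n = n0
    for t in range(v.size):
        out[t] = g_k * n**4 * (v[t] - e_k)
        r = biophysics.rates_scalar(v[t])
        n += dt_ms * (r[4] * (1.0 - n) - r[5] * n)
    return out


def pseudo_generator_energy(pg_voltage: VoltageTrace, params: BiophysParams,
                            mode: Literal["signed", "rectified"] = "signed"
                            ) -> EnergyReport:
    """Energy of a pseudo-generator trace.

    The K⁺ current implied by the interpolated voltage is recomputed with
    deterministic delayed-rectifier gating driven by that voltage (started
    from its steady state at the first sample), plus the K⁺ leak branch.
    """
    v = pg_voltage.values
    _, _, n0 = biophysics.steady_state(float(v[0]))
    ik = _det_n_current(v, pg_voltage.dt * 1e3, n0, params.g_k_max, params.e_k)
    g_lk, _ = split_leak(params.g_leak, params.e_leak, params.e_k, params.e_na)
    ik = ik + g_lk * (v - params.e_k)
    duration = pg_voltage.duration
    atp = atp_consumption(ik, params.area, duration, pg_voltage.dt, mode)
    charge = float(ik.sum()) * pg_voltage.dt * params.area * UM2_TO_CM2 * 1e-6
    return EnergyReport(charge, atp)
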