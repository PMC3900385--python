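"""Biophysical constants, gating kinetics and Markov channel schemes.

Everything downstream — the integrator, the Gillespie engine, the energy
accounting — pulls its membrane parameters and voltage-dependent rate
functions from here.  The parameter set is the standard squid-axon
Hodgkin–Huxley set in the modern voltage convention (rest near −65 mV,
E_K = −77 mV), with single-channel counts fixed by the canonical densities
of 60 Na⁺/µm² and 18 K⁺/µm² on a 100 µm² patch.

Units: mV, ms, ms⁻¹, µF/cm², mS/cm², µA/cm², µm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import yaml
from numba import njit

# Rate-function indices shared with the simulation kernel.
ALPHA_M, BETA_M, ALPHA_H, BETA_H, ALPHA_N, BETA_N = range(6)

N_NA_STATES = 8   # m0..m3 x h0..h1
N_K_STATES = 5    # n0..n4
NA_OPEN = 7       # m3h1
K_OPEN = 4        # n4


@dataclass(frozen=True)
class BiophysParams:
    """Membrane constants of the single 100 µm² compartment.

    ``n_na``/``n_k`` are the stochastic channel counts; maximal conductances
    are specific (per cm²), so the single-channel conductance implied by the
    defaults is 20 pS for both species.
    """

    membrane_capacitance: float = 1.0    # µF/cm²
    g_na_max: float = 120.0              # mS/cm²
    g_k_max: float = 36.0                # mS/cm²
    g_leak: float = 0.3                  # mS/cm²
    e_na: float = 50.0                   # mV
    e_k: float = -77.0                   # mV
    e_leak: float = -54.4                # mV
    area: float = 100.0                  # µm²
    n_na: int = 6000
    n_k: int = 1800

    def __post_init__(self) -> None:
        for name in ("g_na_max", "g_k_max", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.e_k < self.e_leak < self.e_na):
            raise ValueError("require E_K < E_leak < E_Na")
        if self.n_na <= 0 or self.n_k <= 0:
            raise ValueError("channel counts must be positive")
        if self.area <= 0:
            raise ValueError("area must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BiophysParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@njit(cache=True)
def _vtrap(x: float, y: float) -> float:
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0."""
    u = x / y
    if abs(u) < 1e-6:
        return y * (1.0 + 0.5 * u)
    return x / (1.0 - math.exp(-u))


@njit(cache=True)
def rates_scalar(v: float) -> tuple[float, float, float, float, float, float]:
    """The six HH transition rates (ms⁻¹) at membrane potential ``v`` (mV).

    JIT-compiled so the simulation kernel can call it directly.
    """
    alpha_m = 0.1 * _vtrap(v + 40.0, 10.0)
    beta_m = 4.0 * math.exp(-(v + 65.0) / 18.0)
    alpha_h = 0.07 * math.exp(-(v + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    alpha_n = 0.01 * _vtrap(v + 55.0, 10.0)
    beta_n = 0.125 * math.exp(-(v + 65.0) / 80.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


@dataclass(frozen=True)
class GatingRates:
    """The six voltage-dependent transition rates at one potential (ms⁻¹)."""

    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha_m, self.beta_m, self.alpha_h, self.beta_h,
             self.alpha_n, self.beta_n]
        )


def gating_rates(v: float) -> GatingRates:
    """Evaluate all six gating rates at ``v`` (mV); raises on non-finite input."""
    if not math.isfinite(v):
        raise ValueError(f"membrane potential must be finite, got {v}")
    r = GatingRates(*rates_scalar(v))
    assert min(r.as_array()) >= 0.0
    return r


def steady_state(v: float) -> tuple[float, float, float]:
    """(m∞, h∞, n∞) at potential ``v``: x∞ = α/(α+β) per gate."""
    am, bm, ah, bh, an, bn = rates_scalar(v)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def time_constants(v: float) -> tuple[float, float, float]:
    """(τ_m, τ_h, τ_n) in ms: τ = 1/(α+β) per gate."""
    am, bm, ah, bh, an, bn = rates_scalar(v)
    return 1.0 / (am + bm), 1.0 / (ah + bh), 1.0 / (an + bn)


@dataclass(frozen=True)
class Transition:
    src: str
    dst: str
    rate_index: int      # which of the six base rates
    multiplicity: int    # combinatorial factor from remaining subunits

    def rate(self, v: float) -> float:
        return self.multiplicity * rates_scalar(v)[self.rate_index]


@dataclass(frozen=True)
class ChannelScheme:
    """Markov gating scheme: an ordered state list and rate-labelled edges.

    The Na⁺ scheme is the 8-state m_i h_j lattice (i = 0..3 activated m
    subunits, j = 0/1 de-/inactivated h subunit) with 20 edges; the K⁺
    scheme is the 5-state n_i chain with 8 edges.  Exactly one state
    conducts: m3h1 respectively n4.
    """

    channel_kind: str
    states: tuple[str, ...]
    conducting_state: str
    transitions: tuple[Transition, ...]

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def conducting_index(self) -> int:
        return self.states.index(self.conducting_state)

    def state_index(self, label: str) -> int:
        return self.states.index(label)

    def rate_matrix(self, v: float) -> np.ndarray:
        """Generator matrix Q (ms⁻¹) at frozen potential ``v`` (Q[i, j] is
        the i→j rate; diagonal holds minus the total outflow)."""
        n = self.n_states
        q = np.zeros((n, n))
        for t in self.transitions:
            i, j = self.state_index(t.src), self.state_index(t.dst)
            q[i, j] += t.rate(v)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def equilibrium(self, v: float) -> np.ndarray:
        """Stationary occupancy distribution at frozen potential ``v``."""
        q = self.rate_matrix(v)
        # null vector of Q^T with sum-to-one constraint
        a = np.vstack([q.T, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        p, *_ = np.linalg.lstsq(a, b, rcond=None)
        p = np.clip(p, 0.0, None)
        return p / p.sum()


def build_channel_scheme(kind: str) -> ChannelScheme:
    """Construct the Na⁺ (8 states / 20 edges) or K⁺ (5 states / 8 edges)
    activation lattice; together they give the 13-state, 28-edge system."""
    if kind == "Na":
        states = tuple(f"m{i}h{j}" for j in (0, 1) for i in range(4))
        trans: list[Transition] = []
        for j in (0, 1):
            for i in range(3):
                trans.append(Transition(f"m{i}h{j}", f"m{i+1}h{j}", ALPHA_M, 3 - i))
                trans.append(Transition(f"m{i+1}h{j}", f"m{i}h{j}", BETA_M, i + 1))
        for i in range(4):
            trans.append(Transition(f"m{i}h0", f"m{i}h1", ALPHA_H, 1))
            trans.append(Transition(f"m{i}h1", f"m{i}h0", BETA_H, 1))
        return ChannelScheme("Na", states, "m3h1", tuple(trans))
    if kind == "K":
        states = tuple(f"n{i}" for i in range(5))
        trans = []
        for i in range(4):
            trans.append(Transition(f"n{i}", f"n{i+1}", ALPHA_N, 4 - i))
            trans.append(Transition(f"n{i+1}", f"n{i}", BETA_N, i + 1))
        return ChannelScheme("K", states, "n4", tuple(trans))
    raise ValueError(f"unknown channel kind {kind!r}")


def na_equilibrium(v: float) -> np.ndarray:
    """Closed-form stationary Na occupancies: Binom(3, m∞) ⊗ Bernoulli(h∞),
    ordered as the scheme's states (h0 row first)."""
    m, h, _ = steady_state(v)
    binom = np.array([math.comb(3, i) * m**i * (1 - m) ** (3 - i) for i in range(4)])
    return np.concatenate([(1 - h) * binom, h * binom])


def k_equilibrium(v: float) -> np.ndarray:
    """Closed-form stationary K occupancies: Binom(4, n∞)."""
    _, _, n = steady_state(v)
    return np.array([math.comb(4, i) * n**i * (1 - n) ** (4 - i) for i in range(5)])


def combined_transition_arrays() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten both schemes into parallel (src, dst, rate_index, multiplicity)
    arrays over a 13-long joint state vector (Na states 0–7, K states 8–12);
    this is the table the Gillespie kernel walks."""
    na = build_channel_scheme("Na")
    k = build_channel_scheme("K")
    src, dst, rid, mult = [], [], [], []
    for t in na.transitions:
        src.append(na.state_index(t.src))
        dst.append(na.state_index(t.dst))
        rid.append(t.rate_index)
        mult.append(t.multiplicity)
    for t in k.transitions:
        src.append(8 + k.state_index(t.src))
        dst.append(8 + k.state_index(t.dst))
        rid.append(t.rate_index)
        mult.append(t.multiplicity)
    return (np.array(src, np.int64), np.array(dst, np.int64),
            np.array(rid, np.int64), np.array(mult, np.float64))


def resting_potential(params: BiophysParams, with_na: bool = True,
                      holding_current: float = 0.0) -> float:
    """Deterministic resting potential: root of the steady-state I–V curve."""
    from scipy.optimize import brentq

    def net_current(v: float) -> float:
        m, h, n = steady_state(v)
        i = params.g_k_max * n**4 * (v - params.e_k)
        i += params.g_leak * (v - params.e_leak)
        if with_na:
            i += params.g_na_max * m**3 * h * (v - params.e_na)
        return holding_current - i

    return brentq(net_current, -90.0, -40.0, xtol=1e-10)
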