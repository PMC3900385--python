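"""Hybrid integrator for the single-compartment membrane equation.

The membrane potential is advanced by forward Euler at a fixed 10 µs
step.  Deterministic channel populations advance their gating variables
by Euler on dx/dt = α(1−x) − β(x); stochastic populations advance by an
exact Gillespie walk over the Markov scheme within each step, with
transition rates frozen at the step's voltage (the standard hybrid for
voltage-dependent channel noise: the potential moves little per 10 µs).
The joint Na⁺/K⁺ system has 13 states and 28 transitions; the walk
selects among whichever transitions belong to stochastic populations.

The inner loops are JIT-compiled with numba; a single 1 s trial of the
fully stochastic 6000-Na/1800-K compartment involves on the order of
10⁷ channel transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from numba import njit

from . import biophysics
from .biophysics import BiophysParams
from .stimulus import CurrentTrace

Mode = Literal["stochastic", "deterministic", "absent"]
_MODE_CODE = {"stochastic": 0, "deterministic": 1, "absent": 2}

SPIKE_THRESHOLD_MV = -20.0
SPIKE_DEAD_TIME_MS = 2.0
DEFAULT_BURN_IN_S = 0.1


class SimulationDiverged(RuntimeError):
    """Voltage left the physical range / went non-finite; carries the step."""

    def __init__(self, step: int):
        super().__init__(f"voltage diverged at step {step}")
        self.step = step


@dataclass(frozen=True)
class ModelConfig:
    """Which conductances exist and whether each fluctuates.

    The four model variants are (na_mode, k_mode) =
    (stochastic, stochastic)  — the spiking neuron model,
    (deterministic, stochastic) and (stochastic, deterministic) — the
    channel-swap controls, and (absent, stochastic) — the graded model.
    """

    params: BiophysParams = field(default_factory=BiophysParams)
    na_mode: Mode = "stochastic"
    k_mode: Mode = "stochastic"
    dt: float = 1e-5          # s
    initial_v: Optional[float] = None   # None -> deterministic rest
    seed: int = 0

    def __post_init__(self) -> None:
        if self.na_mode not in ("stochastic", "deterministic", "absent"):
            raise ValueError(f"bad na_mode {self.na_mode!r}")
        if self.k_mode not in ("stochastic", "deterministic"):
            raise ValueError(f"bad k_mode {self.k_mode!r}")

    @property
    def is_graded(self) -> bool:
        return self.na_mode == "absent"


@dataclass
class VoltageTrace:
    values: np.ndarray
    dt: float   # s

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def duration(self) -> float:
        return self.values.size * self.dt


@dataclass
class ChannelStateCounts:
    """Occupancies of the stochastic schemes plus deterministic gates."""

    na: Optional[np.ndarray] = None   # 8 ints, sum = N_Na
    k: Optional[np.ndarray] = None    # 5 ints, sum = N_K
    m: float = 0.0
    h: float = 0.0
    n: float = 0.0


@dataclass
class SimulationResult:
    voltage: VoltageTrace
    open_fraction_na: np.ndarray
    open_fraction_k: np.ndarray
    config: ModelConfig
    stimulus: CurrentTrace
    seed: int

    @property
    def dt(self) -> float:
        return self.voltage.dt

    def current_na(self) -> np.ndarray:
        p = self.config.params
        return p.g_na_max * self.open_fraction_na * (self.voltage.values - p.e_na)

    def current_k(self) -> np.ndarray:
        """Delayed-rectifier K⁺ current (µA/cm², outward positive)."""
        p = self.config.params
        return p.g_k_max * self.open_fraction_k * (self.voltage.values - p.e_k)

    def current_leak(self) -> np.ndarray:
        p = self.config.params
        return p.g_leak * (self.voltage.values - p.e_leak)


_rates_nb = biophysics.rates_scalar


@njit(cache=True)
def _gillespie_window(counts, r6, src, dst, rid, mult, window, a):
    """Advance ``counts`` through one window (ms) of the exact Markov walk.

    Propensity a_j = multiplicity_j · rate_j(V) · counts[src_j]; waiting
    times are exponential in the total propensity λ; the transition is
    selected with probability a_j/λ.  Residual waiting time beyond the
    window boundary is discarded (rates are refreshed next step).
    """
    ntrans = src.size
    t_rem = window
    while True:
        lam = 0.0
        for j in range(ntrans):
            a[j] = mult[j] * r6[rid[j]] * counts[src[j]]
            lam += a[j]
        if lam <= 0.0:
            return
        t_trans = -math.log(np.random.random()) / lam
        if t_trans >= t_rem:
            return
        t_rem -= t_trans
        u = np.random.random() * lam
        c = 0.0
        jsel = ntrans - 1
        for j in range(ntrans):
            c += a[j]
            if u <= c:
                jsel = j
                break
        counts[src[jsel]] -= 1
        counts[dst[jsel]] += 1


@njit(cache=True)
def _simulate_kernel(stim, dt_ms, cm, gna, gk, gl, ena, ek, el,
                     nna, nk, na_mode, k_mode,
                     src, dst, rid, mult,
                     counts, m, h, n, v0, seed):
    np.random.seed(seed)
    nsteps = stim.size
    v_out = np.empty(nsteps)
    fna = np.empty(nsteps)
    fk = np.empty(nsteps)
    a = np.empty(src.size)
    v = v0
    stochastic = src.size > 0
    for t in range(nsteps):
        am, bm, ah, bh, an, bn = _rates_nb(v)
        if stochastic:
            r6 = np.empty(6)
            r6[0] = am; r6[1] = bm; r6[2] = ah
            r6[3] = bh; r6[4] = an; r6[5] = bn
            _gillespie_window(counts, r6, src, dst, rid, mult, dt_ms, a)
        if na_mode == 1:
            m += dt_ms * (am * (1.0 - m) - bm * m)
            h += dt_ms * (ah * (1.0 - h) - bh * h)
        if k_mode == 1:
            n += dt_ms * (an * (1.0 - n) - bn * n)

        if na_mode == 0:
            f_na = counts[7] / nna
        elif na_mode == 1:
            f_na = m * m * m * h
        else:
            f_na = 0.0
        if k_mode == 0:
            f_k = counts[12] / nk
        else:
            f_k = n * n * n * n

        v_out[t] = v
        fna[t] = f_na
        fk[t] = f_k
        i_mem = (gna * f_na * (v - ena) + gk * f_k * (v - ek)
                 + gl * (v - el))
        v = v + dt_ms * (stim[t] - i_mem) / cm
        if not math.isfinite(v) or v > 200.0 or v < -200.0:
            return v_out, fna, fk, t
    return v_out, fna, fk, -1


from functools import lru_cache


@lru_cache(maxsize=4)
def _active_transitions(na_stoch: bool, k_stoch: bool):
    src, dst, rid, mult = biophysics.combined_transition_arrays()
    keep = np.zeros(src.size, bool)
    keep[:20] = na_stoch
    keep[20:] = k_stoch
    return src[keep], dst[keep], rid[keep], mult[keep]


def equilibrium_counts(model: ModelConfig, v: float,
                       rng: np.random.Generator) -> ChannelStateCounts:
    """Initial state: occupancies multinomial at the stationary law, gates
    at their steady-state values."""
    p = model.params
    m, h, n = biophysics.steady_state(v)
    counts = ChannelStateCounts(m=m, h=h, n=n)
    if model.na_mode == "stochastic":
        counts.na = rng.multinomial(p.n_na, biophysics.na_equilibrium(v)).astype(np.int64)
    if model.k_mode == "stochastic":
        counts.k = rng.multinomial(p.n_k, biophysics.k_equilibrium(v)).astype(np.int64)
    return counts


def simulate(model: ModelConfig, stimulus: CurrentTrace,
             seed: Optional[int] = None,
             burn_in: float = DEFAULT_BURN_IN_S) -> SimulationResult:
    """Integrate the compartment's response to ``stimulus``.

    ``burn_in`` seconds of constant current (the stimulus' first sample)
    are prepended, simulated, and discarded, so the returned traces start
    from the stationary response rather than the initialisation
    transient.  Same seed ⇒ bit-identical result.
    """
    if abs(stimulus.dt - model.dt) > 1e-12:
        raise ValueError("stimulus dt must match model dt")
    p = model.params
    if seed is None:
        seed = model.seed
    ss = np.random.SeedSequence(seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    kernel_seed = int(np.random.default_rng(ss.spawn(2)[1]).integers(2**31))

    v0 = (model.initial_v if model.initial_v is not None
          else biophysics.resting_potential(p, with_na=not model.is_graded))
    state = equilibrium_counts(model, v0, init_rng)
    joint = np.zeros(13, np.int64)
    if state.na is not None:
        joint[:8] = state.na
    if state.k is not None:
        joint[8:] = state.k
    src, dst, rid, mult = _active_transitions(model.na_mode == "stochastic",
                                              model.k_mode == "stochastic")

    n_burn = round(burn_in / model.dt)
    stim_arr = stimulus.values
    if n_burn:
        stim_arr = np.concatenate([np.full(n_burn, stimulus.values[0]), stim_arr])

    v, fna, fk, status = _simulate_kernel(
        stim_arr, model.dt * 1e3, p.membrane_capacitance,
        0.0 if model.is_graded else p.g_na_max, p.g_k_max, p.g_leak,
        p.e_na, p.e_k, p.e_leak, p.n_na, p.n_k,
        _MODE_CODE[model.na_mode], _MODE_CODE[model.k_mode],
        src, dst, rid, mult, joint, state.m, state.h, state.n,
        v0, kernel_seed)
    if status >= 0:
        raise SimulationDiverged(status - n_burn)
    sl = slice(n_burn, None)
    return SimulationResult(VoltageTrace(v[sl], model.dt), fna[sl], fk[sl],
                            model, stimulus, seed)


def gillespie_update(counts: ChannelStateCounts, v: float, window: float,
                     seed: int, params: Optional[BiophysParams] = None) -> ChannelStateCounts:
    """Advance the stochastic occupancies through one ``window`` (ms) at
    frozen potential ``v`` — the production kernel exposed for one step."""
    r6 = np.array(biophysics.rates_scalar(v))
    joint = np.zeros(13, np.int64)
    if counts.na is not None:
        joint[:8] = counts.na
    if counts.k is not None:
        joint[8:] = counts.k
    src, dst, rid, mult = _active_transitions(counts.na is not None,
                                              counts.k is not None)
    _seed_nb(int(seed) % 2**31)
    _gillespie_window(joint, r6, src, dst, rid, mult, window,
                      np.empty(src.size))
    out = ChannelStateCounts(m=counts.m, h=counts.h, n=counts.n)
    if counts.na is not None:
        out.na = joint[:8].copy()
    if counts.k is not None:
        out.k = joint[8:].copy()
    return out


@njit(cache=True)
def _seed_nb(seed):
    np.random.seed(seed)


def detect_spikes(voltage: VoltageTrace,
                  threshold: float = SPIKE_THRESHOLD_MV,
                  dead_time: float = SPIKE_DEAD_TIME_MS) -> np.ndarray:
    """Spike times (s): upward threshold crossings at least ``dead_time``
    (ms) apart.  Unambiguous for ~100 mV action potentials."""
    v = voltage.values
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return np.empty(0)
    dead = dead_time * 1e-3
    times = crossings * voltage.dt
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= dead:
            kept.append(t)
    return np.asarray(kept)


def firing_rate(voltage: VoltageTrace, **kw) -> float:
    return detect_spikes(voltage, **kw).size / voltage.duration
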