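"""Band-limited Gaussian white-noise current stimuli.

This is the synthetic-data generator for every experiment: 300 Hz
Gaussian white noise shaped by a 40th-order Butterworth low-pass
(realised in second-order sections — a direct-form filter of that order
is numerically unstable), re-scaled to the target standard deviation
after filtering, presented as 1 s trials.  "Frozen" sessions repeat the
identical realisation on every trial (for noise-entropy and
signal/noise splits); "unfrozen" sessions draw an independent
realisation per trial.  Optional broadband extrinsic noise is added at
a configured signal-to-noise ratio Ω (noise variance = signal
variance / Ω) and is regenerated per trial even under frozen signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class StimulusConfig:
    mean: float = 0.0          # µA/cm²
    sd: float = 1.0            # µA/cm²
    cutoff: float = 300.0      # Hz
    filter_order: int = 40
    duration: float = 1.0      # s
    dt: float = 1e-5           # s
    n_trials: int = 60
    frozen: bool = False
    snr: Optional[float] = None   # Ω; None = no extrinsic noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.cutoff >= 0.5 / self.dt:
            raise ValueError("cutoff must lie below the Nyquist frequency")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")

    @property
    def n_samples(self) -> int:
        return round(self.duration / self.dt)


@dataclass
class CurrentTrace:
    """Uniformly sampled injected-current waveform (µA/cm²)."""

    values: np.ndarray
    dt: float                       # s
    metadata: Optional[StimulusConfig] = None

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    def copy(self) -> "CurrentTrace":
        return CurrentTrace(self.values.copy(), self.dt, self.metadata)


# settle the causal filter on this much extra noise before the trial starts
_PAD_SECONDS = 0.1


def _one_realization(config: StimulusConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_samples
    if config.sd == 0.0:
        return np.full(n, config.mean)
    pad = round(_PAD_SECONDS / config.dt)
    white = rng.standard_normal(n + pad)
    sos = signal.butter(config.filter_order, config.cutoff,
                        btype="low", fs=1.0 / config.dt, output="sos")
    shaped = signal.sosfilt(sos, white)[pad:]
    shaped -= shaped.mean()
    shaped *= config.sd / shaped.std()
    return shaped + config.mean


def band_limited_noise(config: StimulusConfig) -> list[CurrentTrace]:
    """Generate one CurrentTrace per trial under ``config``.

    Frozen sessions reuse the first child seed for the signal on every
    trial; extrinsic noise (if ``config.snr`` is set) is drawn from a
    fresh child seed per trial regardless.
    """
    ss = np.random.SeedSequence(config.seed)
    signal_seeds, noise_seeds = ss.spawn(2)
    sig_children = signal_seeds.spawn(config.n_trials)
    noi_children = noise_seeds.spawn(config.n_trials)

    traces = []
    frozen_values = None
    for k in range(config.n_trials):
        if config.frozen:
            if frozen_values is None:
                frozen_values = _one_realization(
                    config, np.random.default_rng(sig_children[0]))
            values = frozen_values.copy()
        else:
            values = _one_realization(config, np.random.default_rng(sig_children[k]))
        trace = CurrentTrace(values, config.dt, config)
        if config.snr is not None:
            trace = add_extrinsic_noise(trace, config.snr,
                                        np.random.default_rng(noi_children[k]))
        traces.append(trace)
    return traces


def add_extrinsic_noise(trace: CurrentTrace, snr: float, seed) -> CurrentTrace:
    """Add unfiltered broadband Gaussian noise with variance σ²_signal/Ω."""
    if snr is None or not np.isfinite(snr):
        return trace.copy()
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma2 = np.var(trace.values)
    noise = rng.standard_normal(trace.values.size) * np.sqrt(sigma2 / snr)
    return CurrentTrace(trace.values + noise, trace.dt, trace.metadata)


class HoldingCurrentError(RuntimeError):
    """Raised when a holding target cannot be reached without spiking."""


def find_holding_current(model, target_mean_v: float, tolerance: float = 0.5,
                         duration: float = 2.0, burn_in: float = 0.2,
                         seed: int = 0, max_iter: int = 40) -> float:
    """Tonic current (µA/cm²) holding the mean membrane potential at target.

    Starts from the deterministic steady-state estimate and bisects on the
    simulated mean voltage (``duration`` seconds after ``burn_in``).  For
    Na⁺-bearing models a spiking probe marks its current as too
    depolarising; a target that spikes even at the analytic estimate is
    reported as unreachable.
    """
    from . import biophysics
    from .simulate import VoltageTrace, detect_spikes, simulate as run_sim

    params = model.params
    with_na = model.na_mode != "absent"
    m, h, n = biophysics.steady_state(target_mean_v)
    est = params.g_k_max * n**4 * (target_mean_v - params.e_k)
    est += params.g_leak * (target_mean_v - params.e_leak)
    if with_na:
        est += params.g_na_max * m**3 * h * (target_mean_v - params.e_na)

    def probe(current: float) -> tuple[float, int]:
        # common random numbers across probes keep mean V monotone in I
        n_samp = round((duration + burn_in) / model.dt)
        stim = CurrentTrace(np.full(n_samp, current), model.dt)
        res = run_sim(model, stim, seed=seed, burn_in=0.0)
        keep = slice(round(burn_in / model.dt), None)
        v = res.voltage.values[keep]
        spikes = detect_spikes(VoltageTrace(v, model.dt))
        return float(v.mean()), spikes.size

    lo, hi = est - 1.0, est + 1.0
    mean_lo, spk_lo = probe(lo)
    if with_na and spk_lo:
        raise HoldingCurrentError(
            f"target {target_mean_v} mV unreachable: spiking at I={lo:.3f}")
    mean_hi, spk_hi = probe(hi)
    # widen until the target is bracketed (mean V increases with current)
    for _ in range(8):
        if mean_lo > target_mean_v:
            lo -= 1.0
            mean_lo, _ = probe(lo)
        elif mean_hi < target_mean_v and not spk_hi:
            hi += 1.0
            mean_hi, spk_hi = probe(hi)
        else:
            break

    best, best_err = lo, abs(mean_lo - target_mean_v)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        mean_mid, spk_mid = probe(mid)
        if with_na and spk_mid:
            hi = mid
            continue
        err = abs(mean_mid - target_mean_v)
        if err < best_err:
            best, best_err = mid, err
        if err <= tolerance:
            return mid
        if mean_mid < target_mean_v:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    if best_err <= tolerance:
        return best
    raise HoldingCurrentError(
        f"holding search did not reach {target_mean_v} mV within "
        f"{tolerance} mV (best error {best_err:.2f} mV)")
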