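"""Gaussian-channel information bound for analogue voltage responses.

From a frozen-noise session the signal is the across-trial mean response
and the noise is each trial's residual about that mean.  Signal and
noise power spectra are estimated with a multitaper estimator (Slepian
tapers, time-bandwidth NW = 3, 5 tapers, averaged over trials), and the
information rate is the Shannon capacity of an additive Gaussian
channel, ∫ log₂(1 + SNR(f)) df integrated by the trapezoid rule over
0–300 Hz.  Because Gaussian noise maximises entropy at fixed variance,
the bound is an upper bound when the residuals are non-Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.signal import windows


@lru_cache(maxsize=8)
def _tapers(n: int, nw: float, k: int) -> np.ndarray:
    return windows.dpss(n, nw, Kmax=k)

from .simulate import VoltageTrace

DEFAULT_BAND = (0.0, 300.0)
DEFAULT_NW = 3.0
DEFAULT_N_TAPERS = 5


@dataclass
class SpectralEstimate:
    frequencies: np.ndarray    # Hz
    signal_psd: np.ndarray
    noise_psd: np.ndarray
    nw: float = DEFAULT_NW
    n_tapers: int = DEFAULT_N_TAPERS
    n_trials: Optional[int] = None   # None: analytic spectra (no sampling noise)

    @property
    def snr(self) -> np.ndarray:
        return self.signal_psd / np.maximum(self.noise_psd, 1e-300)


@dataclass
class InfoResult:
    rate: float                 # bits/s
    spectral: SpectralEstimate
    band: tuple[float, float] = DEFAULT_BAND


def _as_array(trace) -> np.ndarray:
    return trace.values if hasattr(trace, "values") else np.asarray(trace, float)


def signal_noise_split(frozen_trials: Sequence) -> tuple[np.ndarray, list[np.ndarray]]:
    """Signal = pointwise trial mean; noise_i = trial_i − signal."""
    if len(frozen_trials) < 2:
        raise ValueError("need at least 2 frozen trials")
    arrays = [_as_array(t) for t in frozen_trials]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("frozen trials must have equal length")
    stack = np.stack(arrays)
    mean = stack.mean(axis=0)
    return mean, [row - mean for row in stack]


def multitaper_psd(x: np.ndarray, dt: float, nw: float = DEFAULT_NW,
                   n_tapers: int = DEFAULT_N_TAPERS) -> tuple[np.ndarray, np.ndarray]:
    """One-sided multitaper PSD (unit²/Hz) of a single record."""
    x = np.asarray(x, float)
    n = x.size
    tapers = _tapers(n, nw, n_tapers)   # rows have unit energy
    spec = np.fft.rfft(tapers * x[None, :], axis=1)
    psd = (2.0 * dt) * (spec.real**2 + spec.imag**2).mean(axis=0)
    psd[0] /= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, dt)
    return freqs, psd


def multitaper_csd(x: np.ndarray, y: np.ndarray, dt: float,
                   nw: float = DEFAULT_NW,
                   n_tapers: int = DEFAULT_N_TAPERS) -> tuple[np.ndarray, np.ndarray]:
    """One-sided multitaper cross-spectral density of two records."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    tapers = _tapers(x.size, nw, n_tapers)
    fx = np.fft.rfft(tapers * x[None, :], axis=1)
    fy = np.fft.rfft(tapers * y[None, :], axis=1)
    csd = (2.0 * dt) * (fx * fy.conj()).mean(axis=0)
    csd[0] /= 2.0
    if x.size % 2 == 0:
        csd[-1] /= 2.0
    return np.fft.rfftfreq(x.size, dt), csd


def spectral_estimate(frozen_trials: Sequence, dt: Optional[float] = None,
                      nw: float = DEFAULT_NW,
                      n_tapers: int = DEFAULT_N_TAPERS) -> SpectralEstimate:
    """Signal/noise PSDs of a frozen-noise session."""
    if dt is None:
        dt = frozen_trials[0].dt
    mean, residuals = signal_noise_split(frozen_trials)
    n = len(residuals)
    freqs, sig_psd = multitaper_psd(mean, dt, nw, n_tapers)
    noise_psd = np.mean([multitaper_psd(r, dt, nw, n_tapers)[1] for r in residuals],
                        axis=0)
    # unbiased spectra from n frozen trials: residuals about the trial mean
    # deflate the noise PSD by (n-1)/n, and the mean response carries a
    # residual noise floor of noise/n
    noise_psd = noise_psd * n / (n - 1)
    sig_psd = np.clip(sig_psd - noise_psd / n, 0.0, None)
    return SpectralEstimate(freqs, sig_psd, noise_psd, nw, n_tapers, n)


def gaussian_info(spec: SpectralEstimate,
                  band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Trapezoidal ∫ log₂(1 + SNR(f)) df over ``band`` → bits/s.

    When the spectra come from a finite-trial multitaper estimate
    (``spec.n_trials`` set), the concavity of log(1+x) biases the naive
    integrand low by ½·Var[ŝ]·|d²/ds² log₂(1+s)|; the delta-method term
    (ŝ/(1+ŝ))²·(1/K + 1/(K·n))/(2 ln 2) is added back.  Analytic spectra
    are integrated as-is.
    """
    f = spec.frequencies
    if band[0] < f[0] - 1e-9 or band[1] > f[-1] + 1e-9:
        raise ValueError("band outside the frequency grid")
    mask = (f >= band[0]) & (f <= band[1])
    s = spec.snr[mask]
    integrand = np.log2(1.0 + s)
    if spec.n_trials is not None:
        rel_var = 1.0 / spec.n_tapers + 1.0 / (spec.n_tapers * spec.n_trials)
        integrand = integrand + (s / (1.0 + s)) ** 2 * rel_var / (2.0 * np.log(2.0))
    return float(np.trapezoid(integrand, f[mask]))


def analog_info_pipeline(frozen_trials: Sequence, dt: Optional[float] = None,
                         band: tuple[float, float] = DEFAULT_BAND,
                         nw: float = DEFAULT_NW,
                         n_tapers: int = DEFAULT_N_TAPERS) -> InfoResult:
    """Split → multitaper spectra → Gaussian-channel bound, in one call."""
    spec = spectral_estimate(frozen_trials, dt, nw, n_tapers)
    return InfoResult(gaussian_info(spec, band), spec, band)


def qq_against_gaussian(trace) -> tuple[np.ndarray, np.ndarray]:
    """Quantile–quantile data for checking the Gaussianity the channel
    bound assumes: returns (theoretical standard-normal quantiles, sorted
    standardised samples), ready for plotting."""
    from scipy import stats

    x = np.sort(_as_array(trace))
    x = (x - x.mean()) / x.std()
    probs = (np.arange(1, x.size + 1) - 0.5) / x.size
    return stats.norm.ppf(probs), x


def voltage_noise_sd(model, holding_v: float, duration: float = 2.0,
                     seed: int = 0, tolerance: float = 0.5,
                     burn_in: float = 0.2) -> float:
    """SD of the intrinsic voltage noise (mV) at a held potential.

    Injects the tonic current holding the mean potential at ``holding_v``
    and measures the voltage SD with no further stimulus; raises if the
    held trace spikes (Na⁺-bearing models above threshold).
    """
    from .simulate import detect_spikes, simulate as run_sim
    from .stimulus import CurrentTrace, HoldingCurrentError, find_holding_current

    hold = find_holding_current(model, holding_v, tolerance=tolerance, seed=seed)
    n = round((duration + burn_in) / model.dt)
    res = run_sim(model, CurrentTrace(np.full(n, hold), model.dt),
                  seed=seed + 1, burn_in=0.0)
    v = res.voltage.values[round(burn_in / model.dt):]
    if model.na_mode != "absent" and detect_spikes(VoltageTrace(v, model.dt)).size:
        raise HoldingCurrentError(f"spiking while held at {holding_v} mV")
    return float(v.std())
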