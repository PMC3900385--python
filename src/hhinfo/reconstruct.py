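"""Linear (Wiener) stimulus reconstruction, coherence and nRMSE.

The reverse filter G_rev(f) = ⟨S·R*⟩ / ⟨R·R*⟩ is fitted on the first
65% of trials (spectral averages over trials with the same multitaper
settings as the analogue-information module) and applied to the
held-out 35%.  Reconstruction quality on the test trials is scored by
the coherence γ²(f) between original and reconstructed stimulus, the
coherence information −∫ log₂(1−γ²(f)) df over 0–300 Hz, and the
root-mean-square error normalised by the stimulus SD (nRMSE).
Responses may be voltage traces or 0/1 spike vectors at the simulation
resolution; every record is centred before spectral estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .analog_info import DEFAULT_BAND, DEFAULT_NW, DEFAULT_N_TAPERS, _tapers

_GAMMA_CLIP = 1.0 - 1e-12


@dataclass
class WienerFilters:
    frequencies: np.ndarray
    forward: np.ndarray        # complex, stimulus → response
    reverse: np.ndarray        # complex, response → stimulus
    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    dt: float
    nw: float = DEFAULT_NW
    n_tapers: int = DEFAULT_N_TAPERS


@dataclass
class ReconstructionResult:
    estimates: list[np.ndarray]
    frequencies: np.ndarray
    coherence: np.ndarray      # γ²(f) on the test trials
    nrmse: float
    coherence_info: float      # bits/s
    band: tuple[float, float] = DEFAULT_BAND


def _as_array(x) -> np.ndarray:
    return x.values if hasattr(x, "values") else np.asarray(x, float)


def _tapered_ffts(x: np.ndarray, nw: float, k: int) -> np.ndarray:
    return np.fft.rfft(_tapers(x.size, nw, k) * x[None, :], axis=1)


def _avg_cross(xs: Sequence[np.ndarray], ys: Sequence[np.ndarray],
               nw: float, k: int) -> np.ndarray:
    """⟨X·Y*⟩ averaged over tapers and trials (unnormalised density)."""
    acc = None
    for x, y in zip(xs, ys):
        fx = _tapered_ffts(x, nw, k)
        fy = _tapered_ffts(y, nw, k)
        term = (fx * fy.conj()).mean(axis=0)
        acc = term if acc is None else acc + term
    return acc / len(xs)


def fit_reverse_filter(stimuli: Sequence, responses: Sequence,
                       split: float = 0.65, dt: Optional[float] = None,
                       nw: float = DEFAULT_NW,
                       n_tapers: int = DEFAULT_N_TAPERS) -> WienerFilters:
    """Fit forward/reverse Wiener filters on the first ``split`` fraction
    of trials; the remainder is reserved for testing."""
    if dt is None:
        dt = stimuli[0].dt
    n_trials = len(stimuli)
    if n_trials != len(responses):
        raise ValueError("stimulus/response trial counts differ")
    n_train = max(int(round(split * n_trials)), 1)
    if n_train < 3:
        raise ValueError("need at least 3 training trials")
    if n_train >= n_trials:
        raise ValueError("no trials left for testing")
    train = tuple(range(n_train))
    test = tuple(range(n_train, n_trials))
    s_tr = [_centered(_as_array(stimuli[i])) for i in train]
    r_tr = [_centered(_as_array(responses[i])) for i in train]
    s_r = _avg_cross(s_tr, r_tr, nw, n_tapers)
    r_r = _avg_cross(r_tr, r_tr, nw, n_tapers).real
    s_s = _avg_cross(s_tr, s_tr, nw, n_tapers).real
    if not np.any(r_r > 0):
        raise ValueError("zero response power in band")
    reverse = s_r / np.maximum(r_r, 1e-300)
    forward = s_r.conj() / np.maximum(s_s, 1e-300)
    freqs = np.fft.rfftfreq(s_tr[0].size, dt)
    return WienerFilters(freqs, forward, reverse, train, test, dt, nw, n_tapers)


def _centered(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def apply_reverse(filters: WienerFilters, response) -> np.ndarray:
    """ŝ(t) = F⁻¹[ G_rev(f) · R(f) ]."""
    r = _centered(_as_array(response))
    return np.fft.irfft(filters.reverse * np.fft.rfft(r), n=r.size)


def reconstruct_and_score(filters: WienerFilters, test_stimuli: Sequence,
                          test_responses: Sequence,
                          band: tuple[float, float] = DEFAULT_BAND) -> ReconstructionResult:
    """Reconstruct held-out stimuli and score coherence / info / nRMSE."""
    if len(test_stimuli) != len(test_responses) or len(test_stimuli) == 0:
        raise ValueError("mismatched or empty test set")
    s_te = [_centered(_as_array(s)) for s in test_stimuli]
    estimates = [apply_reverse(filters, r) for r in test_responses]
    nw, k = filters.nw, filters.n_tapers
    s_sh = _avg_cross(s_te, estimates, nw, k)
    s_s = _avg_cross(s_te, s_te, nw, k).real
    sh_sh = _avg_cross(estimates, estimates, nw, k).real
    gamma2 = (s_sh.real**2 + s_sh.imag**2) / np.maximum(s_s * sh_sh, 1e-300)
    if np.any(gamma2 > 1.0 + 1e-9):
        warnings.warn("coherence exceeded 1; clipping", RuntimeWarning)
    gamma2 = np.clip(gamma2, 0.0, _GAMMA_CLIP)
    f = filters.frequencies
    mask = (f >= band[0]) & (f <= band[1])
    info = float(np.trapezoid(-np.log2(1.0 - gamma2[mask]), f[mask]))
    errs = [np.sqrt(np.mean((s - e) ** 2)) / max(s.std(), 1e-300)
            for s, e in zip(s_te, estimates)]
    return ReconstructionResult(estimates, f, gamma2, float(np.mean(errs)),
                                info, band)


def wiener_pipeline(stimuli: Sequence, responses: Sequence,
                    split: float = 0.65, dt: Optional[float] = None,
                    band: tuple[float, float] = DEFAULT_BAND,
                    nw: float = DEFAULT_NW,
                    n_tapers: int = DEFAULT_N_TAPERS) -> ReconstructionResult:
    """Fit on the first 65% of trials, score on the rest."""
    filters = fit_reverse_filter(stimuli, responses, split, dt, nw, n_tapers)
    return reconstruct_and_score(
        filters,
        [stimuli[i] for i in filters.test_indices],
        [responses[i] for i in filters.test_indices],
        band)


def spikes_to_binary(train: np.ndarray, duration: float, dt: float) -> np.ndarray:
    """Spike times → 0/1 vector at the simulation resolution."""
    n = round(duration / dt)
    vec = np.zeros(n)
    idx = np.floor(np.asarray(train) / dt).astype(int)
    vec[idx[(idx >= 0) & (idx < n)]] = 1.0
    return vec
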