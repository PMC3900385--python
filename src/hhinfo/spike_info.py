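"""Direct-method information rate of spike trains.

Spike trains are discretised into 1 ms letters (0 = silent, 1 = at least
one spike) and grouped into K-letter words.  The total entropy rate is
estimated from unfrozen-noise trials (every word start, pooled across
trials); the noise entropy rate from frozen-noise trials (a word
distribution across trials at each start time, averaged over starts).
Both plug-in entropies receive the first-order Treves–Panzeri
(Miller–Madow) sample-size correction, and both curves are extrapolated
to infinite word length by a straight-line fit of entropy rate against
1/(K·Δt) over the most linear four contiguous word lengths.  The
information rate is the difference of the two intercepts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

DEFAULT_K_SET = (2, 4, 6, 8, 12, 16, 24, 32, 48, 64)
DEFAULT_DELTA_T = 1e-3   # s


@dataclass
class WordDistribution:
    """Counts of binary K-letter words (word encoded as an integer)."""

    delta_t: float
    K: int
    counts: dict[int, int]
    context: Literal["total", "per-time-slice"] = "total"

    @property
    def n_words(self) -> int:
        return sum(self.counts.values())

    def probabilities(self) -> np.ndarray:
        c = np.fromiter(self.counts.values(), float)
        return c / c.sum()


@dataclass
class EntropyEstimate:
    total_entropy_rate: float          # bits/s, extrapolated
    noise_entropy_rate: float          # bits/s, extrapolated
    info_rate: float                   # bits/s, clamped at 0
    info_rate_raw: float               # bits/s, unclamped
    k_set: tuple[int, ...]
    total_per_k: np.ndarray            # bits/s at each K (bias-corrected)
    noise_per_k: np.ndarray
    total_fit: dict = field(default_factory=dict)
    noise_fit: dict = field(default_factory=dict)


def letters_from_train(train: np.ndarray, duration: float,
                       delta_t: float = DEFAULT_DELTA_T) -> np.ndarray:
    """Binary letter sequence: 1 where a bin of width Δt contains ≥1 spike."""
    n_bins = round(duration / delta_t)
    idx = np.floor(np.asarray(train) / delta_t).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    letters = np.zeros(n_bins, np.uint8)
    letters[idx] = 1
    return letters


def _word_codes(letters: np.ndarray, K: int) -> np.ndarray:
    """Integer codes of all K-letter words at every start position."""
    if letters.size < K:
        raise ValueError("trial shorter than one word")
    win = np.lib.stride_tricks.sliding_window_view(letters.astype(np.uint64), K)
    powers = (np.uint64(1) << np.arange(K, dtype=np.uint64))[::-1]
    return win @ powers


def words_from_trains(trains: Sequence[np.ndarray], duration: float,
                      delta_t: float = DEFAULT_DELTA_T, K: int = 8,
                      mode: Literal["unfrozen", "frozen"] = "unfrozen"):
    """Word statistics of a trial set.

    ``unfrozen`` pools words over every start position and trial into one
    WordDistribution; ``frozen`` returns one WordDistribution per start
    time, each taken across trials (the basis of the noise entropy).
    """
    if len(trains) == 0:
        raise ValueError("empty train set")
    codes = np.stack([
        _word_codes(letters_from_train(t, duration, delta_t), K) for t in trains
    ])   # (n_trials, n_starts)
    if mode == "unfrozen":
        vals, cts = np.unique(codes.ravel(), return_counts=True)
        return WordDistribution(delta_t, K, dict(zip(vals.tolist(), cts.tolist())),
                                "total")
    dists = []
    for t in range(codes.shape[1]):
        vals, cts = np.unique(codes[:, t], return_counts=True)
        dists.append(WordDistribution(delta_t, K,
                                      dict(zip(vals.tolist(), cts.tolist())),
                                      "per-time-slice"))
    return dists


def _entropy_bits(counts: np.ndarray, corrected: bool) -> float:
    n = counts.sum()
    p = counts / n
    h = float(-(p * np.log2(p)).sum())
    if corrected:
        # first-order (Treves–Panzeri / Miller–Madow) correction of the
        # negative sampling bias of the plug-in estimator
        h += (np.count_nonzero(counts) - 1) / (2.0 * n * math.log(2.0))
    return h


def entropy_rate(dist: WordDistribution, corrected: bool = True) -> float:
    """Word entropy divided by word duration K·Δt → bits/s."""
    counts = np.fromiter(dist.counts.values(), float)
    return _entropy_bits(counts, corrected) / (dist.K * dist.delta_t)


def _most_linear_intercept(x: np.ndarray, y: np.ndarray, n_points: int = 4):
    """Straight-line intercept at x→0 using the contiguous ``n_points``
    subset with the smallest RMS fit residual."""
    if x.size < n_points:
        raise ValueError(f"need at least {n_points} word lengths")
    best = None
    for start in range(x.size - n_points + 1):
        xs, ys = x[start:start + n_points], y[start:start + n_points]
        slope, intercept = np.polyfit(xs, ys, 1)
        resid = float(np.sqrt(np.mean((np.polyval([slope, intercept], xs) - ys) ** 2)))
        if best is None or resid < best["residual"]:
            best = {"slope": float(slope), "intercept": float(intercept),
                    "residual": resid, "k_subset": list(range(start, start + n_points))}
    return best


def _plug_in_bits(samples: np.ndarray, corrected: bool = True) -> float:
    """Word entropy of a sample vector: plug-in plus the first-order
    Treves–Panzeri term (the residual O(1/N²) bias is removed by the
    sample-size extrapolation layered on top)."""
    s = np.sort(samples)
    edges = np.flatnonzero(s[1:] != s[:-1])
    counts = np.diff(np.concatenate([[0], edges + 1, [s.size]])).astype(float)
    p = counts / s.size
    h = float(-(p * np.log2(p)).sum())
    if corrected:
        h += (counts.size - 1) / (2.0 * s.size * math.log(2.0))
    return h


_SUBSAMPLE_GROUPS = (1, 2, 4)
_N_PARTITIONS = 2


def _canonical_trial_order(codes: np.ndarray) -> np.ndarray:
    """Row order that depends only on the trial contents (so estimates are
    invariant to how the trial list was assembled)."""
    return codes[np.argsort([row.tobytes() for row in codes], kind="stable")]


def _partitions(codes: np.ndarray, g: int):
    """Disjoint trial groups of size n//g, from a couple of shuffles seeded
    by the trial contents (order-invariant, trials exchangeable)."""
    import zlib
    n = codes.shape[0]
    sz = n // g
    if g == 1:
        yield np.arange(n)
        return
    rng = np.random.default_rng(zlib.crc32(codes.tobytes()))
    for _ in range(_N_PARTITIONS):
        perm = rng.permutation(n)
        for i in range(g):
            yield perm[i * sz:(i + 1) * sz]


def _size_extrapolated(xs: list[float], hs: list[float]) -> float:
    """Intercept of H(1/N) at 1/N → 0 (polynomial through the points);
    removes the O(1/N) sampling bias of the plug-in entropy and most of
    the next order."""
    if len(xs) == 1:
        return hs[0]
    return float(np.polyval(np.polyfit(xs, hs, len(xs) - 1), 0.0))


def _total_entropy_bits(codes: np.ndarray) -> float:
    """Pooled word entropy of an unfrozen session, bias-corrected by
    extrapolating over trial-subset sizes."""
    codes = _canonical_trial_order(codes)
    n = codes.shape[0]
    xs, hs = [], []
    for g in _SUBSAMPLE_GROUPS:
        sz = n // g
        if sz < 2 and g > 1:
            break
        vals = [_plug_in_bits(codes[idx].ravel())
                for idx in _partitions(codes, g)]
        xs.append(1.0 / (sz * codes.shape[1]))
        hs.append(float(np.mean(vals)))
    return _size_extrapolated(xs, hs)


def _noise_entropy_bits(codes: np.ndarray) -> float:
    """Mean per-start-time word entropy of a frozen session, with the same
    trial-subset size extrapolation applied per time slice."""
    codes = _canonical_trial_order(codes)
    n = codes.shape[0]
    xs, hs = [], []
    for g in _SUBSAMPLE_GROUPS:
        sz = n // g
        if sz < 2 and g > 1:
            break
        vals = []
        for idx in _partitions(codes, g):
            sub = codes[idx]
            vals.append(np.mean([_plug_in_bits(sub[:, t])
                                 for t in range(sub.shape[1])]))
        xs.append(1.0 / sz)
        hs.append(float(np.mean(vals)))
    return _size_extrapolated(xs, hs)


def direct_method_info(frozen_trains: Sequence[np.ndarray],
                       unfrozen_trains: Sequence[np.ndarray],
                       duration: float,
                       delta_t: float = DEFAULT_DELTA_T,
                       k_set: Sequence[int] = DEFAULT_K_SET) -> EntropyEstimate:
    """Total/noise entropy rates per word length, extrapolated to K→∞."""
    if len(frozen_trains) < 2 or len(unfrozen_trains) < 2:
        raise ValueError("need at least 2 trials per session")
    k_set = tuple(k_set)
    total = np.empty(len(k_set))
    noise = np.empty(len(k_set))
    for i, K in enumerate(k_set):
        unfrozen_codes = np.stack([
            _word_codes(letters_from_train(t, duration, delta_t), K)
            for t in unfrozen_trains])
        total[i] = _total_entropy_bits(unfrozen_codes) / (K * delta_t)
        frozen_codes = np.stack([
            _word_codes(letters_from_train(t, duration, delta_t), K)
            for t in frozen_trains])
        noise[i] = _noise_entropy_bits(frozen_codes) / (K * delta_t)
    inv_t = 1.0 / (np.asarray(k_set) * delta_t)   # 1/s, decreasing in K
    total_fit = _most_linear_intercept(inv_t, total)
    noise_fit = _most_linear_intercept(inv_t, noise)
    raw = total_fit["intercept"] - noise_fit["intercept"]
    return EntropyEstimate(
        total_entropy_rate=total_fit["intercept"],
        noise_entropy_rate=noise_fit["intercept"],
        info_rate=max(raw, 0.0), info_rate_raw=raw,
        k_set=k_set, total_per_k=total, noise_per_k=noise,
        total_fit=total_fit, noise_fit=noise_fit)
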