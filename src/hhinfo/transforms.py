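"""Pseudo-generator potentials and action-potential footprint insertion.

``pseudo_generator`` excises each action potential from a voltage trace
and bridges the gap with a straight line — a 6 ms window anchored 1 ms
before the threshold crossing (removing the upstroke) and 5 ms after.
The result approximates the generator potential that drove the spikes.

``insert_footprints`` mimics those excisions in arbitrary (typically
graded) responses: 6 ms interpolations, at least 10 ms between window
starts, placed identically in every trial (*deterministic*), identically
up to ±4 ms of per-window uniform jitter (*jittered*), or independently
per trial (*random*).  ``interpolate_stimulus`` applies the same windows
to the stimulus, which isolates the information genuinely blanked out by
the footprint from the stimulus–response mismatch it creates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .simulate import VoltageTrace
from .stimulus import CurrentTrace

PSEUDO_WIDTH_MS = 6.0
PSEUDO_PRE_MS = 1.0


@dataclass(frozen=True)
class FootprintPlan:
    scheme: Literal["deterministic", "jittered", "random"] = "random"
    n_per_second: int = 10
    width: float = 6.0        # ms
    min_gap: float = 10.0     # ms between window starts
    jitter_max: float = 4.0   # ms
    apply_to_stimulus: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("deterministic", "jittered", "random"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def _interpolate_windows(values: np.ndarray, dt: float,
                         windows: Sequence[tuple[float, float]]) -> np.ndarray:
    """Replace each [start, stop) window (s) by the line joining the edge
    samples; windows beyond the trace are truncated to the boundary."""
    out = values.copy()
    n = values.size
    for start, stop in windows:
        i0 = max(int(round(start / dt)), 0)
        i1 = min(int(round(stop / dt)), n - 1)
        if i1 <= i0:
            continue
        out[i0:i1 + 1] = np.linspace(out[i0], out[i1], i1 - i0 + 1)
    return out


def _merge(windows: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for start, stop in sorted(windows):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append([start, stop])
    return [tuple(w) for w in merged]


def pseudo_generator(voltage: VoltageTrace, spikes: np.ndarray,
                     width: float = PSEUDO_WIDTH_MS,
                     pre: float = PSEUDO_PRE_MS) -> VoltageTrace:
    """Excise each spike with a ``width`` ms linear interpolation.

    The window spans [t − pre, t + (width − pre)] around each threshold
    crossing; overlapping windows are merged into one interpolation.
    """
    wins = [((t - pre * 1e-3), (t + (width - pre) * 1e-3)) for t in np.atleast_1d(spikes)]
    values = _interpolate_windows(voltage.values, voltage.dt, _merge(wins))
    return VoltageTrace(values, voltage.dt)


def _base_positions(duration: float, plan: FootprintPlan,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniformly random admissible window starts (s): n starts in
    [0, duration − width] with pairwise start gaps ≥ min_gap, sampled by
    the gap construction (uniform order statistics plus fixed spacers),
    which stays exact even near the packing limit."""
    n = plan.n_per_second * duration
    if abs(n - round(n)) > 1e-9:
        raise ValueError("n_per_second × duration must be an integer")
    n = int(round(n))
    width_s, gap_s = plan.width * 1e-3, plan.min_gap * 1e-3
    slack = (duration - width_s) - (n - 1) * gap_s
    if slack < 0:
        raise ValueError(
            f"cannot pack {n} windows with {plan.min_gap} ms start gaps "
            f"into {duration} s")
    u = np.sort(rng.uniform(0.0, slack, size=n))
    return u + gap_s * np.arange(n)


def _grid_positions(duration: float, plan: FootprintPlan) -> np.ndarray:
    """Evenly spaced window starts (the footprints of a perfectly regular
    spike train at n_per_second)."""
    n = int(round(plan.n_per_second * duration))
    spacing = duration / n
    width_s, gap_s = plan.width * 1e-3, plan.min_gap * 1e-3
    if spacing < gap_s:
        raise ValueError(
            f"cannot pack {n} windows with {plan.min_gap} ms start gaps "
            f"into {duration} s")
    starts = (np.arange(n) + 0.5) * spacing - width_s / 2.0
    return np.clip(starts, 0.0, duration - width_s)


def plan_positions(duration: float, n_trials: int,
                   plan: FootprintPlan) -> list[np.ndarray]:
    """Per-trial window start times (s) under the plan's scheme.

    ``deterministic``: a regular grid, identical in every trial.
    ``jittered``: the grid plus up to ±jitter_max per window — one shared
    realisation used in every trial (timing wanders off the grid but stays
    reproducible across trials, so no trial-to-trial variance is added).
    ``random``: independent admissible positions per trial.
    """
    rng = np.random.default_rng(plan.seed)
    gap_s = plan.min_gap * 1e-3
    if plan.scheme == "deterministic":
        base = _grid_positions(duration, plan)
        return [base.copy() for _ in range(n_trials)]
    if plan.scheme == "jittered":
        base = _grid_positions(duration, plan)
        jmax = plan.jitter_max * 1e-3
        # sequential draw inside the feasible interval: the gap constraint
        # survives any jitter because base gaps are >= gap + jitter slack
        pos = np.empty(base.size)
        prev = -np.inf
        for i, b in enumerate(base):
            lo = max(b - jmax, prev + gap_s, 0.0)
            hi = min(b + jmax, duration - plan.width * 1e-3)
            pos[i] = rng.uniform(lo, hi) if hi > lo else lo
            prev = pos[i]
        return [pos.copy() for _ in range(n_trials)]
    return [_base_positions(duration, plan, rng) for _ in range(n_trials)]


def insert_footprints(traces: Sequence[VoltageTrace], plan: FootprintPlan
                      ) -> tuple[list[VoltageTrace], list[np.ndarray]]:
    """Insert linear-interpolation footprints into every trial.

    Returns the modified traces and the per-trial window start times, so
    the same windows can be applied to the stimulus.
    """
    duration = traces[0].values.size * traces[0].dt
    positions = plan_positions(duration, len(traces), plan)
    width_s = plan.width * 1e-3
    out = []
    for trace, pos in zip(traces, positions):
        wins = [(p, p + width_s) for p in pos]
        out.append(VoltageTrace(
            _interpolate_windows(trace.values, trace.dt, wins), trace.dt))
    return out, positions


def interpolate_stimulus(stimulus: CurrentTrace, positions: np.ndarray,
                         width: float = 6.0) -> CurrentTrace:
    """Apply the same footprint windows to a stimulus trace."""
    wins = [(p, p + width * 1e-3) for p in np.atleast_1d(positions)]
    return CurrentTrace(
        _interpolate_windows(stimulus.values, stimulus.dt, wins),
        stimulus.dt, stimulus.metadata)
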