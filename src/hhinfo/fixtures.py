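"""Deterministic analytic fixtures for exercising every estimator.

Each named fixture returns the generated data together with the
closed-form values it should reproduce, so the entropy, coherence,
spectral and energy estimators can all be validated without running the
full compartment simulation.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from .simulate import VoltageTrace
from .stimulus import CurrentTrace

_NAMES = ("two_state_channel", "bernoulli_train", "linear_system",
          "constant_current", "triangle_spikes")


def make_fixture(name: str, params: dict[str, Any] | None = None,
                 seed: int = 0) -> dict[str, Any]:
    """Build the named fixture; see the individual builders for contents."""
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if name == "two_state_channel":
        return _two_state_channel(params, rng)
    if name == "bernoulli_train":
        return _bernoulli_train(params, rng)
    if name == "linear_system":
        return _linear_system(params, rng)
    if name == "constant_current":
        return _constant_current(params)
    if name == "triangle_spikes":
        return _triangle_spikes(params)
    raise ValueError(f"unknown fixture {name!r}; known: {_NAMES}")


def _two_state_channel(p, rng):
    """Open/closed channel with rates α (open) and β (close): a Markov
    trajectory sampled at ``dt`` plus the analytic equilibrium α/(α+β)."""
    alpha = p.get("alpha", 1.0)   # ms⁻¹
    beta = p.get("beta", 1.0)
    dt = p.get("dt", 0.01)        # ms
    n_steps = p.get("n_steps", 100_000)
    state = rng.random() < alpha / (alpha + beta)
    states = np.empty(n_steps, np.uint8)
    for t in range(n_steps):
        r = alpha if not state else beta
        if rng.random() < 1.0 - np.exp(-r * dt):
            state = not state
        states[t] = state
    return {"states": states, "dt": dt,
            "expected_open_fraction": alpha / (alpha + beta)}


def _bernoulli_train(p, rng):
    """iid Bernoulli(p) letters as spike times; entropy H(p) bits/letter."""
    prob = p.get("p", 0.5)
    duration = p.get("duration", 60.0)
    delta_t = p.get("delta_t", 1e-3)
    n_bins = round(duration / delta_t)
    letters = rng.random(n_bins) < prob
    spikes = (np.flatnonzero(letters) + 0.5) * delta_t
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(prob * np.log2(prob) + (1 - prob) * np.log2(1 - prob))
    h = float(np.nan_to_num(h))
    return {"spikes": spikes, "duration": duration, "delta_t": delta_t,
            "expected_entropy_per_letter": h,
            "expected_entropy_rate": h / delta_t}


def _linear_system(p, rng):
    """White signal observed in independent white noise.

    response_i = signal + noise_i with equal powers by default, giving an
    analytic per-frequency SNR = P_S/P_N, coherence P_S/(P_S+P_N), and
    Gaussian-channel rate B·log₂(1+SNR)."""
    n = p.get("n_samples", 100_000)
    dt = p.get("dt", 1e-5)
    n_trials = p.get("n_trials", 20)
    sigma_s = p.get("sigma_signal", 1.0)
    sigma_n = p.get("sigma_noise", 1.0)
    band = p.get("band", (0.0, 300.0))
    signal = rng.standard_normal(n) * sigma_s
    trials = [VoltageTrace(signal + rng.standard_normal(n) * sigma_n, dt)
              for _ in range(n_trials)]
    snr = sigma_s**2 / sigma_n**2
    width = band[1] - band[0]
    return {"signal": signal, "trials": trials, "dt": dt,
            "expected_snr": snr,
            "expected_coherence": snr / (1.0 + snr),
            "expected_info_rate": width * np.log2(1.0 + snr)}


def _constant_current(p):
    """Constant outward K⁺ current with its exact ATP/s cost."""
    amplitude = p.get("amplitude", 1.0)    # µA/cm²
    area = p.get("area", 100.0)            # µm²
    duration = p.get("duration", 1.0)
    dt = p.get("dt", 1e-5)
    from .energetics import ELEMENTARY_CHARGE
    n = round(duration / dt)
    charge = amplitude * 1e-6 * area * 1e-8 * duration
    return {"current": np.full(n, amplitude), "area": area,
            "duration": duration, "dt": dt,
            "expected_atp_per_second": charge / ELEMENTARY_CHARGE / 2.0 / duration}


def _triangle_spikes(p):
    """Flat −65 mV baseline with triangular 100 mV transients at known
    times — a detector and pseudo-generator testbed."""
    dt = p.get("dt", 1e-5)
    duration = p.get("duration", 0.1)
    spike_times = np.asarray(p.get("spike_times", [0.02, 0.04, 0.06]))
    half_width = p.get("half_width", 5e-4)
    baseline = p.get("baseline", -65.0)
    t = np.arange(round(duration / dt)) * dt
    v = np.full(t.size, float(baseline))
    for ts in spike_times:
        tri = 100.0 * np.clip(1.0 - np.abs(t - ts) / half_width, 0.0, None)
        v += tri
    return {"voltage": VoltageTrace(v, dt), "spike_times": spike_times,
            "baseline": baseline}
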