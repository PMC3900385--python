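# hhinfo

Information rates and ATP costs of graded versus spiking neural signals,
computed from stochastic Hodgkin–Huxley single-compartment simulations.

## The problem

Most neurons convert analogue voltage signals (synaptic or sensory
*generator potentials*) into trains of action potentials. That conversion
loses information — spike trains are low-dimensional, the Na⁺ channels
that make spikes add noise and nonlinearity, and every action potential
blanks out ~6 ms of the generator potential (its *footprint*) — and it
costs energy, because the large ionic fluxes of spikes must be pumped
back by the Na⁺/K⁺ ATPase. `hhinfo` quantifies both penalties in a
controlled setting: a 100 µm² membrane patch with stochastic voltage-gated
Na⁺ and K⁺ channels (6000 and 1800 channels, exact Gillespie kinetics on
the 13-state, 28-transition Markov scheme), driven by 300 Hz band-limited
Gaussian current noise, compared against the same patch with
deterministic channels or with no Na⁺ channels at all (the graded model).

It is aimed at computational neuroscientists who want a self-contained,
seed-reproducible pipeline for channel-noise simulation, spike-train and
analogue information estimation, and metabolic-cost accounting.

## What it computes

- **Membrane dynamics** — current balance
  `C_m dV/dt = −g_Na m³h (V−E_Na) − g_K n⁴ (V−E_K) − g_leak (V−E_leak) + I(t)`,
  integrated by forward Euler at 10 µs; stochastic channel populations
  advance by an exact Gillespie walk within each step
  (`hhinfo.simulate`).
- **Spike-train information** (direct method, `hhinfo.spike_info`) —
  binary 1 ms letters form K-letter words; total entropy from unfrozen
  trials, noise entropy from frozen trials,
  `R = lim_{T→∞} [H_total(T) − H_noise(T)]/T`, with sample-size bias
  correction and extrapolation to infinite word length.
- **Analogue information** (`hhinfo.analog_info`) — Gaussian-channel
  bound `R = ∫₀³⁰⁰ log₂(1 + S(f)/N(f)) df` from multitaper spectra of the
  frozen-trial mean (signal) and residuals (noise).
- **Linear decoding** (`hhinfo.reconstruct`) — Wiener reverse filter
  `G(f) = ⟨S R*⟩/⟨R R*⟩` fitted on 65% of trials, scored on the rest by
  coherence γ²(f), `R = −∫₀³⁰⁰ log₂(1−γ²(f)) df`, and nRMSE.
- **Footprints and pseudo-generator potentials** (`hhinfo.transforms`) —
  spikes excised by 6 ms linear interpolation; deterministic / jittered /
  random footprint insertion into graded responses.
- **Energy** (`hhinfo.energetics`) — total K⁺ charge (delayed rectifier
  plus the K⁺-permeable leak branch) × N_A/(2F) → ATP/s; efficiency in
  bits per ATP molecule.

## Worked example

```python
from hhinfo import pipeline

spiking = pipeline.spiking_condition(mean=1.0, sd=10.0, n_trials=10, seed=0)
graded  = pipeline.graded_condition(mean=1.0, sd=10.0, n_trials=10, seed=0)
pg      = pipeline.pseudo_generator_condition(spiking)
```

prints (exact values are seed- and trial-budget-dependent):

```
firing rate          : 63.1 spikes/s
spike-train info     : 205 bits/s (3.3 bits/spike)
pseudo-generator info: 1321 bits/s
graded-potential info: 2230 bits/s
spiking cost         : 3.05e+08 ATP/s -> 6.7e-07 bits/ATP
graded cost          : 2.26e+07 ATP/s -> 9.9e-05 bits/ATP
```

The low-mean/high-SD stimulus (1 ± 10 µA/cm², 300 Hz band) drives the
spiking model at ~60 spikes/s carrying ~200 bits/s, while the same patch
without Na⁺ channels carries ~2200 bits/s as a graded signal at a tenth
of the ATP cost — roughly a hundred-fold efficiency gap. The
pseudo-generator potential (spikes cut out) sits in between: the part of
the analogue information destroyed by spiking itself.

A CLI wraps the same pipeline for shell use:

```bash
hhinfo simulate --model graded --mean 1 --sd 10 --trials 10
hhinfo footprint --trials 20 --rates 10,40,80
hhinfo run-experiment --kind grid --preset desk --out results/
```

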