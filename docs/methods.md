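# Methods

## Model

A single isopotential compartment of 100 µm² carries a transient Na⁺
conductance, a delayed-rectifier K⁺ conductance and a passive leak:

    C_m dV/dt = −g_Na·(V−E_Na) − g_K·(V−E_K) − g_leak·(V−E_leak) + I_stim(t) + I_noise(t)

with g_Na = ḡ_Na·(open Na fraction) and g_K = ḡ_K·(open K fraction).
Channel gating follows the classic squid-axon kinetics in the modern
voltage convention. Gating rates are first-order,
x∞ = α/(α+β), τ = 1/(α+β), with the two removable singularities
(α_m at −40 mV, α_n at −55 mV) evaluated by their analytic limits.

Four variants are studied, distinguished by which populations fluctuate:

| variant   | Na⁺            | K⁺             | role |
|-----------|----------------|----------------|------|
| `spiking` | stochastic     | stochastic     | spiking neuron model |
| `det_na`  | deterministic  | stochastic     | channel-swap control |
| `det_k`   | stochastic     | deterministic  | channel-swap control |
| `graded`  | absent         | stochastic     | graded (non-spiking) model |

### Parameters

| symbol | value | units | note |
|--------|-------|-------|------|
| C_m    | 1.0   | µF/cm² | |
| ḡ_Na, ḡ_K, ḡ_leak | 120, 36, 0.3 | mS/cm² | |
| E_Na, E_K, E_leak | 50, −77, −54.4 | mV | rest ≈ −65 mV, threshold ≈ −68 mV |
| area   | 100  | µm² | |
| N_Na, N_K | 6000, 1800 | — | 60 and 18 channels/µm², i.e. 20 pS unitary conductance |

All constants live in `BiophysParams` (YAML round-trip; see
`configs/squid.yaml`), so the set can be swapped without code changes.
Temperature (Q10) scaling and channel cooperativity are out of scope.

### Stochastic channel kinetics

Each Na⁺ channel occupies one of 8 states (m₀..m₃ × h₀/h₁; m₃h₁
conducts), each K⁺ channel one of 5 (n₀..n₄; n₄ conducts): 13 states,
28 voltage-dependent transitions in total, with the multinomial
multiplicities (3−i)α_m / iβ_m etc. Occupancy vectors evolve by the
exact Gillespie algorithm: total propensity λ = Σ aⱼ with
aⱼ = multiplicity·rate(V)·occupancy(source); waiting times
t = −ln(r₁)/λ; transition j chosen with probability aⱼ/λ.

The voltage dependence is handled by the standard hybrid: rates are
frozen at the step's voltage for one 10 µs integration window, events
are executed exactly inside the window, and the residual waiting time is
discarded at the boundary (rates refresh next step). V itself and any
deterministic gates advance by forward Euler. The stationary law of
each scheme at fixed V is the closed-form binomial product
(Binom(3,m∞)×Bern(h∞), Binom(4,n∞)); the test suite checks the engine
against it and against a tight-tolerance RK45 oracle in the
deterministic limit. Initial occupancies are drawn from the stationary
law at rest and 100 ms of burn-in is discarded.

The inner loops are numba-compiled; a 1 s trial of the fully stochastic
model executes ~10⁷ transitions in about a second.

## Stimuli (the synthetic-data generator)

Stimuli are Gaussian white noise low-passed at 300 Hz by a 40th-order
Butterworth filter realised in second-order sections (a direct-form
filter of that order is numerically unstable), then re-standardised to
the target mean and SD — so the configured SD is the delivered SD, not
the pre-filter one. Trials are 1 s at dt = 10 µs; 0.1 s of pre-roll
absorbs the filter transient. Means and SDs span 1–10 µA/cm², the
range over which the compartment moves from integrator-like to
relay-like firing. *Frozen* sessions repeat one realisation across
trials (noise entropy, signal/noise splits); *unfrozen* sessions draw
independent realisations (total entropy, Wiener decoding). Extrinsic
noise, when requested, is unfiltered broadband Gaussian with variance
σ²_signal/Ω and is redrawn per trial even under frozen signals.

Holding experiments add a tonic current found by bisection on the
simulated 2 s mean voltage (0.5 mV default tolerance; common random
numbers across probes keep the bisection monotone), starting from the
deterministic steady-state estimate. For Na⁺-bearing models a spiking
probe marks its current as too depolarising.

What the generator does *not* emulate: naturalistic (non-Gaussian,
adapting) stimulus statistics, conductance-based input, or correlated
mean/SD structure. Conclusions drawn from passing tests therefore
concern this controlled Gaussian stimulus family only.

## Information estimators

### Direct method (spike trains)

Spike times are detected at the −20 mV upward crossing with a 2 ms dead
time (unambiguous for ~100 mV spikes) and binarised into 1 ms letters
(multi-spike bins are negligible below ~90 spikes/s). For each word
length K ∈ {2,4,6,8,12,16,24,32,48,64}: the total entropy rate comes
from the pooled word distribution over every start position of every
unfrozen trial; the noise entropy rate is the mean over start times of
the across-trial word entropy in the frozen session.

Sampling bias is handled in two layers: each entropy is the plug-in
estimate plus the first-order Treves–Panzeri term (occupied−1)/(2N ln2),
and the corrected values are computed on trial subsets of size N, N/2
and N/4 (two content-seeded randomised partitions) and extrapolated to
1/N → 0 by the polynomial through the three points. The first-order
term alone leaves enough residual bias at N = 20–60 trials per time
slice to fabricate ~25 bits/s on stimulus-independent surrogates; the
extrapolation brings that below ~10 bits/s, which is the calibration
the suite asserts. Trial partitions are derived from the sorted trial
contents, so estimates are invariant to trial ordering.

Both entropy-rate curves are then extrapolated to infinite word length:
a straight line in 1/(K·Δt) over the contiguous four-K subset with the
smallest RMS fit residual, the intercept taken at 1/(K·Δt) → 0.
Information = difference of the two intercepts, clamped at zero (the
raw value is reported alongside).

### Gaussian-channel bound (analogue responses)

From a frozen session: signal = across-trial mean, noise = per-trial
residual. Spectra are multitaper estimates (Slepian tapers, NW = 3,
5 tapers — a conventional default, recorded in the output metadata),
averaged over trials for the noise. Two small-sample corrections make
the spectra unbiased: the residual PSD is rescaled by n/(n−1) (residuals
about the trial mean deflate variance) and the noise floor noise/n is
subtracted from the mean-response PSD. The rate is the trapezoidal
∫₀³⁰⁰ log₂(1+SNR(f)) df. Because log(1+x) is concave, the finite-dof
PSD fluctuations bias the naive integrand low by ≈ (s/(1+s))²/(2K ln2)
per Hz; this delta-method term is added back whenever the spectra carry
estimator metadata (analytic spectra are integrated exactly). The
result is an upper bound on the true information when the residuals are
non-Gaussian.

### Wiener reconstruction and coherence information

The reverse filter G(f) = ⟨S·R*⟩/⟨R·R*⟩ is fitted on the first 65% of
trials (cross- and auto-spectra averaged over tapers and trials, same
multitaper settings), applied to the held-out 35%, and scored by the
coherence between original and reconstructed stimulus,
γ²(f) = |⟨S·Ŝ*⟩|²/(⟨S·S*⟩⟨Ŝ·Ŝ*⟩), the information
−∫₀³⁰⁰ log₂(1−γ²) df, and the RMS error normalised by the stimulus SD
about its mean. Records are centred before spectral estimation; spike
responses enter as raw 0/1 vectors at 10 µs (the filter itself performs
the smoothing). γ² is clipped at 1−10⁻¹² with a warning if it exceeds
1 numerically.

## Footprints and pseudo-generator potentials

`pseudo_generator` replaces each spike by the straight line across
[t−1 ms, t+5 ms] (6 ms total — the maximum action-potential width —
anchored ahead of the threshold crossing to remove the upstroke;
overlapping windows merge). `insert_footprints` mimics footprints in
graded responses with 6 ms windows at least 10 ms apart (start-to-start):

- *deterministic* — a regular grid, identical in every trial;
- *jittered* — the grid plus up to ±4 ms per window, one shared
  realisation across trials. Shared jitter is deliberate: independent
  per-trial jitter adds trial-to-trial variance and therefore lowers the
  Gaussian-channel rate by construction, whereas the phenomenon being
  modelled — reliable but imperfectly timed spikes — leaves that rate
  unchanged while still degrading linear decodability;
- *random* — independent admissible positions per trial, sampled by the
  gap construction (uniform order statistics plus fixed 10 ms spacers),
  which remains exact near the packing limit (80/s × 10 ms fills 80% of
  a trial, where rejection sampling stalls).

`interpolate_stimulus` applies the same windows to the stimulus; the
coherence-rate difference between response-only and matched insertion
isolates the information genuinely blanked out by the footprint, and the
footprint loss is expressed relative to the matched rate.

## Energy accounting

The Na⁺/K⁺ pump imports 2 K⁺ per ATP, so ATP/s = Q_K/(2e·T) where Q_K
is the total K⁺ charge: the delayed-rectifier current plus the
K⁺-permeable leak branch. The leak splits uniquely into K⁺- and
Na⁺-permeable branches by solving g_K+g_Na = g_leak and
g_K E_K + g_Na E_Na = g_leak E_leak (≈ 0.2466 / 0.0534 mS/cm² for the
defaults), which reproduces the leak I–V curve identically. The signed
integral is the default (inward K⁺ below E_K genuinely unloads the
pump); a rectified mode is available. Pseudo-generator energy is
recomputed from the interpolated voltage with deterministic
delayed-rectifier gating driven along that voltage — a modelling choice,
since the trace no longer has a unique microscopic channel history.

## Problem sizes, determinism, tolerances

The full protocol uses 60 × 1 s trials per session; the package's desk
preset uses 20 (30 for the direct method, whose noise entropy is the
most sample-hungry quantity), which keeps a complete reproduction run
in minutes while holding estimator error within a few percent for the
analogue quantities and ~10–20% for the direct method. Every stimulus,
initial condition and Gillespie path derives from explicit integer
seeds via spawned `SeedSequence` children; identical seeds give
bit-identical traces and summary tables.

## Known limitations

- The exact parameter table of the original squid-axon variant this
  setup mirrors is not public in the text available to us; the standard
  squid set above is a documented substitution. Quantities dominated by
  near-threshold Na⁺ kinetics inherit the largest model uncertainty —
  most visibly the sub-threshold information of the fully stochastic
  model held at −70 mV, which is acutely sensitive to the distance to
  threshold and to stray near-threshold spikes.
- The Gaussian-channel rate is an upper bound; no entropy-power
  correction for non-Gaussian residuals is applied (a QQ inspection of
  the voltage PDF is the intended diagnostic).
- Binary letters cap the direct method below ~1000 spikes/s regimes;
  fine at the ≤90 spikes/s rates produced here.
- Voltage excursions can exceed [E_K−15, E_Na+5] mV under the most
  hyperpolarising high-SD stimuli, where the nearly leak-only membrane
  is driven far below E_K; this is a property of the model, not an
  integration artefact.
- Single compartment, current input only: no propagation, synaptic
  conductances, bursts or plateau potentials.
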