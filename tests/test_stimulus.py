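import numpy as np
import pytest
from scipy import signal

from hhinfo import biophysics as bp
from hhinfo.simulate import ModelConfig
from hhinfo.stimulus import (CurrentTrace, StimulusConfig, add_extrinsic_noise,
                             band_limited_noise, find_holding_current)


class TestBandLimitedNoise:
    def test_zero_sd_gives_constant_trace(self):
        cfg = StimulusConfig(mean=5.0, sd=0.0, n_trials=2, seed=1)
        for tr in band_limited_noise(cfg):
            assert np.all(tr.values == 5.0)

    def test_frozen_trials_identical_unfrozen_differ(self):
        frozen = band_limited_noise(StimulusConfig(sd=5.0, n_trials=3,
                                                   frozen=True, seed=2))
        assert all(np.array_equal(frozen[0].values, t.values) for t in frozen)
        unfrozen = band_limited_noise(StimulusConfig(sd=5.0, n_trials=3,
                                                     frozen=False, seed=2))
        assert not np.array_equal(unfrozen[0].values, unfrozen[1].values)

    def test_sample_moments_match_config(self):
        cfg = StimulusConfig(mean=3.0, sd=4.0, n_trials=5, seed=3)
        for tr in band_limited_noise(cfg):
            se = 4.0 / np.sqrt(tr.values.size / 300)   # ~300 dof at 300 Hz
            assert abs(tr.values.mean() - 3.0) < 3 * se
            assert abs(tr.values.std() - 4.0) / 4.0 < 0.05

    def test_psd_flat_in_band_and_attenuated_above(self):
        cfg = StimulusConfig(mean=0.0, sd=5.0, n_trials=60, seed=4)
        traces = band_limited_noise(cfg)
        psds = []
        for tr in traces:
            f, p = signal.welch(tr.values, fs=1 / tr.dt, nperseg=2**14)
            psds.append(p)
        psd = np.mean(psds, axis=0)
        band = (f >= 10) & (f <= 250)
        passband = psd[band]
        ratio_db = 10 * np.log10(passband / np.median(passband))
        assert np.all(np.abs(ratio_db) <= 3.0)
        stop = psd[np.argmin(np.abs(f - 400))]
        assert 10 * np.log10(stop / np.median(passband)) <= -60.0

    def test_seed_reproducibility(self):
        cfg = StimulusConfig(sd=2.0, n_trials=2, seed=9)
        a = band_limited_noise(cfg)
        b = band_limited_noise(cfg)
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            StimulusConfig(cutoff=60_000.0)


class TestExtrinsicNoise:
    def test_infinite_snr_is_identity(self):
        tr = CurrentTrace(np.ones(1000), 1e-5)
        out = add_extrinsic_noise(tr, np.inf, 0)
        assert np.array_equal(out.values, tr.values)

    def test_added_variance_matches_omega(self):
        rng = np.random.default_rng(5)
        tr = CurrentTrace(rng.standard_normal(10**6) * 5.0, 1e-5)  # var 25
        out = add_extrinsic_noise(tr, 1.0, 6)
        added = out.values - tr.values
        assert np.var(added) == pytest.approx(25.0, rel=0.05)

    def test_noise_power_scales_inversely_with_omega(self):
        rng = np.random.default_rng(7)
        tr = CurrentTrace(rng.standard_normal(10**6), 1e-5)
        var2 = np.var(add_extrinsic_noise(tr, 2.0, 8).values - tr.values)
        var20 = np.var(add_extrinsic_noise(tr, 20.0, 8).values - tr.values)
        assert var2 / var20 == pytest.approx(10.0, rel=0.1)

    def test_nonpositive_omega_rejected(self):
        tr = CurrentTrace(np.ones(10), 1e-5)
        with pytest.raises(ValueError):
            add_extrinsic_noise(tr, 0.0, 0)


class TestHoldingCurrent:
    def test_graded_rest_needs_no_current(self):
        model = ModelConfig(na_mode="absent", k_mode="stochastic")
        rest = bp.resting_potential(model.params, with_na=False)
        hold = find_holding_current(model, rest, duration=0.5)
        assert abs(hold) < 0.3

    def test_hyperpolarised_target_needs_negative_current(self):
        model = ModelConfig(na_mode="absent", k_mode="stochastic")
        hold = find_holding_current(model, -77.0, duration=0.5)
        assert hold < -2.0

    def test_spiking_model_held_subthreshold_without_spikes(self):
        from hhinfo.simulate import detect_spikes, simulate
        model = ModelConfig()
        hold = find_holding_current(model, -70.0, duration=1.0)
        stim = CurrentTrace(np.full(round(2.0 / model.dt), hold), model.dt)
        res = simulate(model, stim, seed=123)
        assert detect_spikes(res.voltage).size == 0
        assert abs(res.voltage.values.mean() - (-70.0)) < 1.0
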