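import numpy as np
import pytest

from hhinfo import spike_info as si
from hhinfo.fixtures import make_fixture


def bernoulli_trains(p, n_trials, duration, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trials):
        fx = rng.random(round(duration / 1e-3)) < p
        out.append((np.flatnonzero(fx) + 0.5) * 1e-3)
    return out


class TestWords:
    def test_empty_train_concentrates_on_zero_word(self):
        dist = si.words_from_trains([np.array([])], 1.0, K=4, mode="unfrozen")
        assert dist.counts == {0: 997}   # n_bins - K + 1 sliding starts

    def test_periodic_train_has_two_sliding_words(self):
        spikes = np.arange(0, 1.0, 2e-3) + 0.5e-3   # every other 1 ms bin
        dist = si.words_from_trains([spikes], 1.0, K=2, mode="unfrozen")
        assert set(dist.counts) == {0b01, 0b10}
        a, b = dist.counts[0b01], dist.counts[0b10]
        assert abs(a - b) <= 1

    def test_frozen_mode_returns_per_start_distributions(self):
        trains = [np.array([0.0105]), np.array([0.0105])]
        dists = si.words_from_trains(trains, 0.02, K=2, mode="frozen")
        assert len(dists) == 19
        assert all(d.n_words == 2 for d in dists)

    def test_iid_letters_entropy_matches_closed_form(self):
        trains = bernoulli_trains(0.5, 1, 100.0, seed=1)
        dist = si.words_from_trains(trains, 100.0, K=8, mode="unfrozen")
        h_word = si.entropy_rate(dist) * 8 * 1e-3
        assert h_word == pytest.approx(8.0, rel=0.01)

    def test_empty_train_set_rejected(self):
        with pytest.raises(ValueError):
            si.words_from_trains([], 1.0, K=2)


class TestEntropyRate:
    def test_single_word_distribution_is_zero(self):
        d = si.WordDistribution(1e-3, 4, {0: 500})
        assert si.entropy_rate(d, corrected=False) == 0.0

    def test_uniform_words_give_k_bits_per_k_ms(self):
        d = si.WordDistribution(1e-3, 8, {w: 10 for w in range(256)})
        assert si.entropy_rate(d, corrected=False) == pytest.approx(1000.0)

    def test_sparse_bernoulli_rate_near_closed_form(self):
        fx = make_fixture("bernoulli_train", {"p": 0.1, "duration": 60.0}, seed=2)
        dist = si.words_from_trains([fx["spikes"]], 60.0, K=8, mode="unfrozen")
        assert si.entropy_rate(dist) == pytest.approx(fx["expected_entropy_rate"],
                                                      rel=0.02)

    def test_correction_increases_undersampled_entropy(self):
        rng = np.random.default_rng(3)
        words = rng.integers(0, 2**10, size=500)
        vals, cts = np.unique(words, return_counts=True)
        d = si.WordDistribution(1e-3, 10, dict(zip(vals.tolist(), cts.tolist())))
        assert si.entropy_rate(d, corrected=True) > si.entropy_rate(d, corrected=False)


class TestDirectMethod:
    def test_identical_frozen_trials_have_zero_noise_entropy(self):
        train = bernoulli_trains(0.05, 1, 10.0, seed=4)[0]
        frozen = [train.copy() for _ in range(10)]
        unfrozen = bernoulli_trains(0.05, 10, 10.0, seed=5)
        est = si.direct_method_info(frozen, unfrozen, 10.0)
        assert est.noise_entropy_rate == pytest.approx(0.0, abs=1e-9)
        assert est.info_rate == pytest.approx(est.total_entropy_rate)

    def test_stimulus_independent_trains_carry_no_information(self):
        # iid trains in both sessions: total == noise up to estimator error
        frozen = bernoulli_trains(0.05, 60, 1.0, seed=6)
        unfrozen = bernoulli_trains(0.05, 60, 1.0, seed=7)
        est = si.direct_method_info(frozen, unfrozen, 1.0)
        assert abs(est.info_rate_raw) < 10.0

    def test_requires_four_word_lengths(self):
        frozen = bernoulli_trains(0.1, 3, 1.0, seed=8)
        unfrozen = bernoulli_trains(0.1, 3, 1.0, seed=9)
        with pytest.raises(ValueError):
            si.direct_method_info(frozen, unfrozen, 1.0, k_set=(2, 4, 6))

    def test_invariant_to_trial_ordering(self):
        frozen = bernoulli_trains(0.08, 8, 2.0, seed=10)
        unfrozen = bernoulli_trains(0.08, 8, 2.0, seed=11)
        a = si.direct_method_info(frozen, unfrozen, 2.0)
        b = si.direct_method_info(frozen[::-1], unfrozen[::-1], 2.0)
        assert a.total_entropy_rate == b.total_entropy_rate
        assert a.noise_entropy_rate == b.noise_entropy_rate

    def test_extrapolation_recovers_linear_curve(self):
        x = 1.0 / (np.array([2, 4, 6, 8]) * 1e-3)
        y = 100.0 + 0.05 * x
        fit = si._most_linear_intercept(x, y)
        assert fit["intercept"] == pytest.approx(100.0)
        assert fit["slope"] == pytest.approx(0.05)
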