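import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempocode.core_signals import (
    IntervalHistogram,
    SpikeTrain,
    Waveform,
    encode_phase_locked,
    estimate_f0,
    interspike_intervals,
    population_interval_distribution,
)
from tempocode.errors import NoEstimateError, ValidationError

from .conftest import autocorr_f0_oracle, make_tone


class TestWaveform:
    def test_duration(self):
        w = Waveform(np.zeros(800), 8000.0)
        assert w.duration == pytest.approx(0.1)

    def test_rejects_bad_rate(self):
        with pytest.raises(ValidationError):
            Waveform(np.zeros(10), 0.0)

    def test_rejects_empty(self):
        with pytest.raises(ValidationError):
            Waveform(np.array([]), 8000.0)


class TestSpikeTrain:
    def test_empty_is_valid(self):
        st_ = SpikeTrain(np.array([]), 1.0)
        assert len(st_) == 0

    def test_rejects_non_increasing(self):
        with pytest.raises(ValidationError):
            SpikeTrain(np.array([0.1, 0.1]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            SpikeTrain(np.array([0.5, 2.0]), 1.0)


class TestEncodePhaseLocked:
    def test_100hz_sinusoid_zero_crossing(self):
        w = make_tone(100.0, 1.0, 8000.0)
        spikes = encode_phase_locked(w, mode="zero-crossing")
        assert len(spikes) == 100
        assert np.allclose(np.diff(spikes.times), 0.01, atol=1e-6)

    def test_all_zero_waveform_empty(self):
        w = Waveform(np.zeros(8000), 8000.0)
        assert len(encode_phase_locked(w)) == 0

    def test_refractory_skips_alternate_cycles(self):
        # oracle: brute-force cycle-by-cycle simulation of the greedy
        # refractory rule on the known 5 ms crossing grid of a 200 Hz tone
        crossings = np.arange(0.0, 1.0, 1.0 / 200.0)
        expected, last = [], -np.inf
        for t in crossings:
            if t - last >= 7e-3:
                expected.append(t)
                last = t
        w = make_tone(200.0, 1.0, 20000.0)
        spikes = encode_phase_locked(w, refractory=7e-3)
        assert np.allclose(spikes.times, expected, atol=1e-6)
        assert np.mean(np.diff(spikes.times)) == pytest.approx(0.010, abs=1e-6)

    def test_peak_mode(self):
        w = make_tone(100.0, 1.0, 8000.0)
        spikes = encode_phase_locked(w, mode="peak", threshold=0.5)
        assert len(spikes) == 100
        # peaks of sin at 2.5 ms + k*10 ms, sample resolution
        assert np.allclose(spikes.times, 0.0025 + np.arange(100) * 0.01, atol=1.0 / 8000.0)

    def test_rejects_non_finite(self):
        w = Waveform(np.array([0.0, np.nan, 1.0]), 8000.0)
        with pytest.raises(ValidationError):
            encode_phase_locked(w)

    def test_rejects_unknown_mode(self):
        with pytest.raises(ValidationError):
            encode_phase_locked(make_tone(100.0), mode="bogus")


class TestInterspikeIntervals:
    def test_all_order_exhaustive_pairs(self):
        st_ = SpikeTrain(np.array([0.0, 0.010, 0.020]), 0.05)
        h = interspike_intervals(st_, order="all", max_lag=0.05, bin_width=1e-3)
        assert h.counts[10] == 2  # two 10 ms pairs
        assert h.counts[20] == 1  # one 20 ms pair
        assert h.total() == 3

    def test_single_spike_all_zero(self):
        st_ = SpikeTrain(np.array([0.3]), 1.0)
        h = interspike_intervals(st_, order="all", max_lag=0.03, bin_width=1e-4)
        assert h.total() == 0

    def test_first_order_counts_successive_only(self):
        st_ = SpikeTrain(np.array([0.0, 0.010, 0.020]), 0.05)
        h = interspike_intervals(st_, order="first", max_lag=0.05, bin_width=1e-3)
        assert h.counts[10] == 2
        assert h.counts[20] == 0

    def test_poisson_mean_interval(self):
        # analytic oracle: exponential intervals at rate 100/s have mean 10 ms
        rng = np.random.default_rng(11)
        gaps = rng.exponential(1.0 / 100.0, size=11000)
        times = np.cumsum(gaps)
        times = times[times < 100.0]
        st_ = SpikeTrain(times, 100.0)
        h = interspike_intervals(st_, order="first", max_lag=0.2, bin_width=1e-4)
        lags = h.lags() + h.bin_width / 2
        mean = float(np.sum(lags * h.counts) / h.total())
        assert mean == pytest.approx(0.010, rel=0.05)

    def test_all_order_pair_bound(self):
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 0.02, 12))
        times = times[np.diff(np.concatenate([[-1.0], times])) > 1e-4]
        n = times.size
        h = interspike_intervals(SpikeTrain(times, 0.02), order="all", max_lag=0.05, bin_width=1e-3)
        assert h.total() <= n * (n - 1) // 2

    def test_rejects_bad_binning(self):
        with pytest.raises(ValidationError):
            interspike_intervals(SpikeTrain(np.array([0.1]), 1.0), max_lag=1e-4, bin_width=1e-3)


class TestPopulationDistribution:
    def test_additivity_two_identical_trains(self):
        st_ = SpikeTrain(np.arange(0.0, 1.0, 0.01), 1.0)
        single = interspike_intervals(st_, "all", 0.03, 1e-4)
        pooled = population_interval_distribution([st_, st_], "all", 0.03, 1e-4)
        assert np.array_equal(pooled.counts, 2 * single.counts)

    def test_empty_trains_all_zero(self):
        empties = [SpikeTrain(np.array([]), 1.0)] * 3
        h = population_interval_distribution(empties, "all", 0.03, 1e-4)
        assert h.total() == 0

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            population_interval_distribution([], "all", 0.03, 1e-4)

    def test_jittered_200hz_modes_at_multiples_of_5ms(self):
        rng = np.random.default_rng(77)
        trains = []
        for _ in range(50):
            base = np.arange(0.0, 1.0, 1.0 / 200.0)
            times = np.sort(base + rng.normal(0.0, 2e-4, base.size))
            trains.append(SpikeTrain(np.unique(times[times >= 0]), 1.5))
        h = population_interval_distribution(trains, "all", max_lag=0.018, bin_width=1e-4)
        top3 = np.sort(np.argsort(h.counts)[::-1][:6] * h.bin_width)
        # the six heaviest bins straddle 5, 10, 15 ms (noiseless construction)
        for mode in (5e-3, 10e-3, 15e-3):
            assert np.min(np.abs(top3 - mode)) <= 1.5e-4

    @settings(deadline=None, max_examples=20)
    @given(perm_seed=st.integers(0, 1000))
    def test_permutation_invariance(self, perm_seed):
        rng = np.random.default_rng(3)
        trains = [
            SpikeTrain(np.sort(rng.uniform(0, 1, 20 + i)), 1.0) for i in range(4)
        ]
        shuffled = list(np.random.default_rng(perm_seed).permutation(trains))
        h1 = population_interval_distribution(trains, "all", 0.03, 1e-3)
        h2 = population_interval_distribution(shuffled, "all", 0.03, 1e-3)
        assert np.array_equal(h1.counts, h2.counts)


class TestEstimateF0:
    def test_noiseless_100hz(self):
        st_ = SpikeTrain(np.arange(0.0, 1.0, 0.01), 1.0)
        h = interspike_intervals(st_, "all", 0.03, 1e-4)
        assert estimate_f0(h, 50.0, 400.0) == pytest.approx(100.0)

    def test_empty_histogram_no_estimate(self):
        h = interspike_intervals(SpikeTrain(np.array([]), 1.0), "all", 0.03, 1e-4)
        with pytest.raises(NoEstimateError):
            estimate_f0(h, 50.0, 400.0)

    def test_unresolvable_range_rejected(self):
        h = interspike_intervals(SpikeTrain(np.arange(0.0, 1.0, 0.01), 1.0), "all", 0.03, 1e-4)
        with pytest.raises(ValidationError):
            estimate_f0(h, 10.0, 20.0)  # 1/10 s lag beyond max_lag

    @pytest.mark.parametrize("f", [50.0, 130.0, 217.0, 333.0, 400.0])
    def test_pure_tone_matches_autocorrelation_oracle(self, f):
        w = make_tone(f, 1.0, 20000.0)
        spikes = encode_phase_locked(w)
        h = interspike_intervals(spikes, "all", 0.03, 1e-4)
        est = estimate_f0(h, 50.0, 400.0)
        oracle = autocorr_f0_oracle(w, 50.0, 400.0)
        assert abs(1.0 / est - 1.0 / oracle) <= h.bin_width + 1e-9

    def test_periodic_train_histogram_only_at_multiples_of_period(self):
        st_ = SpikeTrain(np.arange(0.0, 1.0, 0.004), 1.0)  # T = 4 ms
        h = interspike_intervals(st_, "all", 0.03, 1e-4)
        nonzero = np.flatnonzero(h.counts) * h.bin_width
        assert nonzero.size > 0
        assert np.all(np.abs(nonzero / 0.004 - np.round(nonzero / 0.004)) < 0.03)


class TestIntervalHistogramType:
    def test_counts_length_invariant(self):
        with pytest.raises(ValidationError):
            IntervalHistogram(1e-4, 0.03, np.zeros(100, dtype=int), "all")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            IntervalHistogram(1e-3, 0.01, -np.ones(10, dtype=int), "all")
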