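"""Burst detection, regime classification and population measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinalcpg import (
    BurstSeries,
    PopulationActivity,
    burst_ratio,
    classify_population_state,
    classify_regime,
    detect_population_bursts,
    population_rate,
    segment_bursts,
    single_neuron_bursts,
    synchrony_index,
)
from spinalcpg.analysis import (
    LABEL_NONE,
    LABEL_STABLE,
    LABEL_TONIC,
    LABEL_UNSTABLE,
    resting_potential,
)
from spinalcpg.engine import SimConfig, SpikeTrain, Trajectory


def make_bursty_train(onsets_s, n_spikes=20, isi_ms=25.0):
    times = []
    for t0 in onsets_s:
        times.extend(t0 * 1000.0 + isi_ms * np.arange(n_spikes))
    return np.asarray(times)


class TestBurstSeries:
    def test_frequency_is_reciprocal_mean_period(self):
        s = BurstSeries(onsets=np.array([0.0, 5.0, 10.0]))
        assert s.mean_period == pytest.approx(5.0)
        assert s.frequency == pytest.approx(0.2)
        assert s.frequency * s.mean_period == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.1, 30.0), min_size=2, max_size=20, unique=True))
    def test_reciprocity_property(self, onsets):
        s = BurstSeries(onsets=np.sort(np.array(onsets)))
        assert s.frequency * s.mean_period == pytest.approx(1.0)

    def test_single_burst_has_no_frequency(self):
        s = BurstSeries(onsets=np.array([2.0]))
        assert s.frequency is None and s.mean_period is None

    def test_unsorted_onsets_rejected(self):
        with pytest.raises(ValueError):
            BurstSeries(onsets=np.array([2.0, 1.0]))


class TestSegmentation:
    def test_regular_tonic_train_is_one_burst(self):
        t = 50.0 * np.arange(1200)  # constant 50 ms ISI for 60 s
        assert len(segment_bursts(t)) == 1

    def test_slow_regular_spiking_is_one_burst(self):
        t = 400.0 * np.arange(100)  # 2.5 Hz regular spiking
        assert len(segment_bursts(t)) == 1

    def test_clean_bursts_recovered(self):
        t = make_bursty_train([0.0, 5.0, 10.0, 15.0])
        bursts = segment_bursts(t)
        assert len(bursts) == 4
        assert [b[0] for b in bursts] == [0.0, 5000.0, 10000.0, 15000.0]

    def test_doublet_merged_into_one_cycle(self):
        # each 5.3 s cycle: main cluster then a trailing clusterlet 0.8 s later
        times = []
        for k in range(8):
            base = k * 5300.0
            times.extend(base + 20.0 * np.arange(20))
            times.extend(base + 800.0 + 20.0 * np.arange(3))
        bursts = segment_bursts(np.array(times))
        assert len(bursts) == 8

    def test_uniform_high_duty_cycle_not_collapsed(self):
        # bursts longer than their gaps: every gap qualifies, so none merge
        times = []
        for k in range(6):
            base = k * 1000.0
            times.extend(base + 10.0 * np.arange(70))  # 700 ms burst, 300 ms gap
        bursts = segment_bursts(np.array(times), gap_ms=200.0)
        assert len(bursts) == 6

    def test_depolarized_pause_merges_clusters(self):
        spikes = np.concatenate([10.0 * np.arange(5), 1500.0 + 10.0 * np.arange(5)])
        spikes = np.concatenate([spikes, 8000.0 + spikes, 16000.0 + spikes])
        t = np.arange(0.0, 20000.0, 1.0)
        plateau = np.full_like(t, -70.0)
        for cycle in (0.0, 8000.0, 16000.0):
            plateau[(t >= cycle) & (t < cycle + 1600.0)] = -45.0
        merged = segment_bursts(spikes, t_ms=t, v=plateau)
        assert len(merged) == 3
        quiescent = np.full_like(t, -70.0)
        assert len(segment_bursts(spikes, t_ms=t, v=quiescent)) == 6

    def test_generator_onsets_recovered_exactly(self):
        # 50 random fixtures; onset of each burst = its first spike
        rng = np.random.default_rng(614615)
        for _ in range(50):
            n_bursts = int(rng.integers(4, 10))
            period = rng.uniform(2.0, 6.0)
            onsets = period * np.arange(n_bursts) + rng.uniform(-0.05, 0.05, n_bursts) * period
            isi = rng.uniform(0.02, 0.08)
            n_spikes = max(2, int(0.3 * period / isi))  # bursts well shorter than cycles
            train = make_bursty_train(onsets, n_spikes=n_spikes, isi_ms=isi * 1000)
            series = single_neuron_bursts(SpikeTrain(0, train))
            assert series.n_bursts == n_bursts
            np.testing.assert_allclose(series.onsets, np.sort(onsets) + 0.0, atol=1e-9)


class TestRegime:
    def test_empty_train_is_silent(self):
        assert classify_regime(SpikeTrain(0, np.array([]))) == "silent"

    def test_bursty_train_is_bursting(self):
        t = make_bursty_train([0.0, 4.0, 8.0])
        assert classify_regime(SpikeTrain(0, t)) == "bursting"

    def test_regular_train_is_tonic(self):
        assert classify_regime(SpikeTrain(0, 50.0 * np.arange(400))) == "tonic"


def test_resting_potential_of_passive_trace():
    t = np.arange(0.0, 30000.0, 1.0)
    v = np.full_like(t, -70.0)
    train = SpikeTrain(0, np.array([]))
    assert resting_potential(t, v, train, "silent") == pytest.approx(-70.0)


class TestPopulationRate:
    def _traj(self, times, ids, n, t1_ms=10000.0):
        cfg = SimConfig(duration=t1_ms / 1000.0, settle=0.001)
        trains = [SpikeTrain(j, np.sort(times[ids == j])) for j in range(n)]
        return Trajectory(t=np.array([t1_ms]), v=None, spikes=trains, config=cfg)

    def test_no_spikes_zero_rate(self):
        traj = self._traj(np.array([]), np.array([], int), 5)
        act = population_rate(traj, n=5, window_ms=(0.0, 10000.0))
        assert np.all(act.rate == 0.0)

    def test_single_bin_normalization(self):
        # 100 spikes from 100 neurons inside one 100 ms bin -> 10 spikes/neuron/s
        times = np.full(100, 450.0)
        ids = np.arange(100)
        act = population_rate(self._traj(times, ids, 100), n=100, window_ms=(0.0, 1000.0))
        assert act.rate[4] == pytest.approx(10.0)
        assert act.rate.sum() == pytest.approx(10.0)

    def test_poisson_rate_recovered(self, rng):
        n, rate_hz, dur_s = 40, 5.0, 50.0
        times, ids = [], []
        for j in range(n):
            k = rng.poisson(rate_hz * dur_s)
            times.append(rng.uniform(0, dur_s * 1000.0, k))
            ids.append(np.full(k, j))
        traj = self._traj(np.concatenate(times), np.concatenate(ids).astype(int), n,
                          t1_ms=dur_s * 1000.0)
        act = population_rate(traj, n=n, window_ms=(0.0, dur_s * 1000.0))
        se = np.sqrt(rate_hz / (n * dur_s))
        assert abs(act.mean_rate - rate_hz) < 3 * se


def square_wave_activity(high=20.0, low=0.0, period_s=2.0, duty=0.5, total_s=40.0):
    bin_s = 0.1
    t = np.arange(bin_s / 2, total_s, bin_s)
    phase = (t % period_s) / period_s
    rate = np.where(phase < duty, high, low)
    return PopulationActivity(t=t, rate=rate, bin_ms=100.0, n=100)


class TestPopulationBursts:
    def test_square_wave_onsets_frequency_amplitude(self):
        act = square_wave_activity()
        series = detect_population_bursts(act)
        assert series.frequency == pytest.approx(0.5, rel=1e-6)
        assert series.amplitude_mean == pytest.approx(20.0)
        # onsets sit at the rising edges (2 s apart)
        assert np.allclose(np.diff(series.onsets), 2.0)

    def test_constant_rate_has_no_bursts(self):
        act = PopulationActivity(t=np.arange(0.05, 40.0, 0.1),
                                 rate=np.full(400, 15.0), bin_ms=100.0, n=100)
        assert detect_population_bursts(act).n_bursts == 0

    def test_manual_threshold_override(self):
        act = square_wave_activity(high=20.0, low=8.0)
        series = detect_population_bursts(act, threshold=10.0)
        assert series.threshold == 10.0
        assert series.frequency == pytest.approx(0.5, rel=1e-6)

    def test_noisy_generator_onsets_within_one_bin(self):
        rng = np.random.default_rng(30)
        for _ in range(50):
            period = rng.uniform(1.5, 4.0)
            n_bursts = int(30.0 / period)
            onsets = period * (1 + np.arange(n_bursts))
            bin_s = 0.1
            t = np.arange(bin_s / 2, 40.0, bin_s)
            rate = np.zeros_like(t)
            for on in onsets:
                rate[(t >= on) & (t < on + period * 0.4)] = rng.uniform(15, 25)
            rate += rng.uniform(0, 0.1 * rate.max(), t.size)  # 10% additive noise
            series = detect_population_bursts(PopulationActivity(t, rate, 100.0, 100))
            assert series.n_bursts == n_bursts
            assert np.max(np.abs(series.onsets - onsets)) <= bin_s + 1e-9


class TestPopulationState:
    def test_unstable_period(self):
        onsets = np.cumsum([1.0, 1.0, 4.0, 1.0, 4.0, 1.0])  # CV >= 0.5
        series = BurstSeries(onsets=onsets, amplitudes=np.full(6, 20.0))
        act = PopulationActivity(np.arange(0.05, 12, 0.1), np.full(120, 5.0), 100.0, 100)
        assert classify_population_state(series, act) == LABEL_UNSTABLE

    def test_low_amplitude(self):
        series = BurstSeries(onsets=np.arange(5.0), amplitudes=np.full(5, 8.0))
        act = PopulationActivity(np.arange(0.05, 5, 0.1), np.full(50, 3.0), 100.0, 100)
        assert classify_population_state(series, act) == LABEL_UNSTABLE

    def test_tonic_sustained_rate(self):
        act = PopulationActivity(np.arange(0.05, 40, 0.1), np.full(400, 15.0), 100.0, 100)
        series = detect_population_bursts(act)
        assert classify_population_state(series, act) == LABEL_TONIC

    def test_quiescent_population(self):
        act = PopulationActivity(np.arange(0.05, 40, 0.1), np.zeros(400), 100.0, 100)
        series = detect_population_bursts(act)
        assert classify_population_state(series, act) == LABEL_NONE

    def test_stable_bursting(self):
        act = square_wave_activity()
        series = detect_population_bursts(act)
        assert classify_population_state(series, act) == LABEL_STABLE

    def test_partition_is_exhaustive(self, rng):
        labels = {LABEL_NONE, LABEL_UNSTABLE, LABEL_STABLE, LABEL_TONIC}
        for _ in range(25):
            t = np.arange(0.05, 30, 0.1)
            rate = np.abs(rng.standard_normal(t.size)) * rng.uniform(0, 30)
            act = PopulationActivity(t, rate, 100.0, 100)
            series = detect_population_bursts(act)
            assert classify_population_state(series, act) in labels


class TestBurstRatio:
    def test_paired_one_to_one(self):
        a = BurstSeries(onsets=np.arange(10.0))
        b = BurstSeries(onsets=np.arange(10.0) + 0.05)
        assert burst_ratio(a, b) in ((1, 1),)

    def test_two_to_one(self):
        a = BurstSeries(onsets=np.arange(0.0, 20.0, 1.0))
        b = BurstSeries(onsets=np.arange(0.0, 20.0, 2.0))
        assert burst_ratio(a, b) == (2, 1)

    def test_three_to_two_interleaving(self):
        a = BurstSeries(onsets=np.arange(0.0, 60.0, 2.0))
        b = BurstSeries(onsets=np.arange(0.0, 60.0, 3.0))
        assert burst_ratio(a, b) == (3, 2)

    def test_empty_series_undefined(self):
        with pytest.raises(ValueError):
            burst_ratio(BurstSeries(onsets=np.array([])), BurstSeries(onsets=np.arange(3.0)))


class TestSynchronyIndex:
    def _traj(self, trains, t1_ms):
        cfg = SimConfig(duration=t1_ms / 1000.0, settle=0.001)
        sts = [SpikeTrain(j, np.sort(tr)) for j, tr in enumerate(trains)]
        return Trajectory(t=np.array([t1_ms]), v=None, spikes=sts, config=cfg)

    def test_identical_bursty_trains_fully_synchronous(self):
        base = make_bursty_train([1.0, 4.0, 7.0, 10.0])
        traj = self._traj([base, base.copy(), base.copy()], 12000.0)
        idx = synchrony_index(traj, window_ms=(0.0, 12000.0))
        assert idx == pytest.approx(1.0)

    def test_independent_poisson_trains_near_zero(self, rng):
        trains = [rng.uniform(0, 60000.0, 600) for _ in range(12)]
        traj = self._traj(trains, 60000.0)
        idx = synchrony_index(traj, window_ms=(0.0, 60000.0))
        assert abs(idx) < 0.1
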