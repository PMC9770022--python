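"""Burst index, PFD-epoch ISI statistics, rate matching, burst
detection, and the velocity-storage time constant."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hddisorient as hdd
from hddisorient.bursts import ISIStats, _facing_epochs
from hddisorient.tracking import HeadDirectionSeries


def constant_train(spikes_per_bin=5, n_bins=120):
    """k evenly spaced spikes in every 1-s bin."""
    return np.concatenate(
        [i + np.linspace(0.05, 0.95, spikes_per_bin) for i in range(n_bins)]
    )


def alternating_train(n_bins=120, high=10):
    """Silent even bins, ``high`` spikes in odd bins."""
    return np.concatenate(
        [i + np.linspace(0.05, 0.95, high) for i in range(1, n_bins, 2)]
    )


class TestBurstIndex:
    def test_constant_rate_scores_zero(self):
        res = hdd.burst_index(constant_train(), (0.0, 120.0))
        assert res.value == 0.0
        assert res.mean_rate == pytest.approx(5.0)

    def test_all_or_nothing_scores_one(self):
        res = hdd.burst_index(alternating_train(), (0.0, 120.0))
        assert res.value == 1.0

    def test_counts_within_band_score_zero(self):
        spikes = np.concatenate([
            0 + np.linspace(0.1, 0.9, 4),
            1 + np.linspace(0.1, 0.9, 5),
            2 + np.linspace(0.1, 0.9, 6),
        ])
        assert hdd.burst_index(spikes, (0.0, 3.0)).value == 0.0

    def test_zero_spikes_degenerate(self):
        res = hdd.burst_index(np.array([]), (0.0, 60.0))
        assert res.value == 0.0
        assert res.degenerate

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(shift=st.integers(1, 50))
    def test_invariant_under_integer_second_shift(self, shift):
        spikes = alternating_train(n_bins=60)
        a = hdd.burst_index(spikes, (0.0, 60.0)).value
        b = hdd.burst_index(spikes + shift, (shift, 60.0 + shift)).value
        assert a == b


class TestIsiStats:
    def _facing_hd(self):
        """30 s facing the PFD (0 deg), 30 s away, 30 s facing again."""
        t = np.arange(0, 90, 1 / 60.0)
        hd = np.where((t < 30) | (t >= 60), 0.0, 180.0)
        return HeadDirectionSeries(t, hd, np.zeros(len(t)))

    def test_no_isis_across_epochs(self):
        hd = self._facing_hd()
        spikes = np.array([1.0, 2.0, 3.0, 61.0, 62.0, 63.0])
        res = hdd.isi_stats(spikes, hd, pfd=0.0, min_isis=1)
        assert len(res.isis) == 4  # 2 per epoch, none across the gap

    def test_all_spikes_outside_field_excluded(self):
        hd = self._facing_hd()
        spikes = 30.0 + np.sort(np.random.default_rng(0).uniform(0, 30, 50))
        res = hdd.isi_stats(spikes, hd, pfd=0.0)
        assert res.excluded
        assert res.n_spikes == 0

    def test_bursty_cell_has_more_short_isis(self):
        hd = self._facing_hd()
        rng = np.random.default_rng(1)
        # same spike count: regular 10 Hz vs 5-spike 100 Hz packets
        regular = np.arange(0.05, 30.0, 0.1)
        packets = np.concatenate(
            [t0 + 0.01 * np.arange(5) for t0 in np.arange(0.1, 30.0, 0.5)]
        )
        r_reg = hdd.isi_stats(regular, hd, pfd=0.0)
        r_bur = hdd.isi_stats(np.sort(packets), hd, pfd=0.0)
        assert r_bur.frac_short > r_reg.frac_short
        assert r_reg.frac_short == 0.0

    def test_pfd_rate_uses_facing_time_only(self):
        hd = self._facing_hd()
        spikes = np.arange(0.5, 30.0, 1.0)  # 30 spikes in first epoch
        res = hdd.isi_stats(spikes, hd, pfd=0.0, min_isis=1)
        assert res.pfd_rate == pytest.approx(30 / 60.0, rel=0.01)

    def test_exclude_until_drops_early_rotations(self):
        hd = self._facing_hd()
        spikes = np.concatenate([np.arange(0.5, 30, 1.0), np.arange(60.5, 90, 1.0)])
        res = hdd.isi_stats(spikes, hd, pfd=0.0, exclude_until=60.0, min_isis=1)
        assert res.n_spikes == 30
        assert res.total_epoch_time == pytest.approx(30.0, rel=0.01)


class TestRateMatch:
    def _stats(self, rate):
        return ISIStats(np.empty(0), np.nan, np.nan, rate, 0, 0.0, False)

    def test_nearest_within_one_hz(self):
        g = [self._stats(10.4)]
        base = [self._stats(9.8), self._stats(10.5)]
        pairs = hdd.rate_match(g, base)
        assert pairs[0][1].pfd_rate == 10.5

    def test_beyond_cap_dropped(self):
        pairs = hdd.rate_match([self._stats(20.0)], [self._stats(15.0)])
        assert pairs == []

    def test_self_match_is_identity(self):
        group = [self._stats(r) for r in (3.0, 7.0, 11.0)]
        pairs = hdd.rate_match(group, group)
        assert all(a.pfd_rate == b.pfd_rate for a, b in pairs)

    def test_repetition_allowed(self):
        base = [self._stats(10.0)]
        pairs = hdd.rate_match([self._stats(9.5), self._stats(10.5)], base)
        assert len(pairs) == 2

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            hdd.rate_match([], [self._stats(1.0)])


class TestDetectBursts:
    def test_single_packet_one_burst(self):
        spikes = 5.0 + np.linspace(0, 0.05, 20)
        bs = hdd.detect_bursts(spikes, (0.0, 10.0))
        assert len(bs) == 1
        assert bs.peak_times[0] == pytest.approx(5.025, abs=0.1)

    def test_periodic_packets_recovered(self):
        spikes = np.concatenate(
            [t0 + np.linspace(0, 0.1, 15) for t0 in (1.0, 3.0, 5.0, 7.0)]
        )
        bs = hdd.detect_bursts(np.sort(spikes), (0.0, 9.0))
        assert 4 <= len(bs) <= 5
        np.testing.assert_allclose(bs.interburst_intervals, 2.0, atol=0.1)
        np.testing.assert_allclose(bs.speed_estimates, 180.0, rtol=0.06)

    def test_sparse_spikes_below_threshold(self):
        spikes = np.arange(0.5, 10.0, 1.0)
        assert len(hdd.detect_bursts(spikes, (0.0, 10.0))) == 0

    def test_count_monotone_in_height_threshold(self):
        rng = np.random.default_rng(7)
        spikes = np.sort(rng.uniform(0, 20, 400))
        counts = [
            len(hdd.detect_bursts(spikes, (0.0, 20.0), min_height=h,
                                  min_prominence=0.0))
            for h in (0.1, 0.3, 0.5, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            hdd.detect_bursts(np.array([0.1]), (0.0, 0.5))


class TestTimeConstant:
    def test_interval_to_speed_conversion(self):
        bs = hdd.BurstSeries(np.array([0.0, 2.0, 5.0]))
        np.testing.assert_allclose(bs.speed_estimates, [180.0, 120.0])

    def test_decay_threshold_for_180(self):
        assert hdd.decay_threshold(180.0) == pytest.approx(66.21, abs=0.01)

    def test_closed_form_construction_recovered_within_5_percent(self):
        period, tau = 2.0, 3.8
        T = [0.0]
        for _ in range(4):
            T.append(T[-1] + period * np.exp(T[-1] / tau))
        fit = hdd.fit_time_constant([np.diff(T)], period)
        assert fit.tau == pytest.approx(tau, rel=0.05)
        assert not fit.excluded

    def test_too_few_intervals_skipped(self):
        assert hdd.fit_time_constant([[2.0]], 2.0) is None
        assert hdd.fit_time_constant([[]], 2.0) is None

    def test_non_decaying_fit_excluded_with_nonpositive_tau(self):
        # intervals shrinking -> speeds increasing -> b > 0
        fit = hdd.fit_time_constant([[4.0, 3.0, 2.0, 1.0]], 2.0)
        assert fit.excluded
        assert fit.tau <= 0

    def test_condition_mean_skips_excluded_cells(self):
        good = hdd.TimeConstantFit(3.5, 300.0, -0.5, 4)
        bad = hdd.TimeConstantFit(-1.0, 100.0, 0.2, 4, excluded=True)
        assert hdd.mean_time_constant([good, bad, None]) == pytest.approx(3.5)
        assert np.isnan(hdd.mean_time_constant([bad]))

    def test_periodic_train_speed_exact(self):
        bs = hdd.BurstSeries(np.arange(0.0, 10.0, 2.0))
        np.testing.assert_allclose(bs.speed_estimates, 180.0)


class TestFacingEpochs:
    def test_wraparound_field(self):
        t = np.arange(0, 2, 1 / 60.0)
        hd = HeadDirectionSeries(t, np.full(len(t), 355.0), np.zeros(len(t)))
        epochs = _facing_epochs(hd, pfd=10.0, half_width=30.0)
        assert len(epochs) == 1
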