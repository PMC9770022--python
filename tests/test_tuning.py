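"""Tuning curves, directional statistics, classification, windowed and
per-revolution tuning."""

import numpy as np
import pytest

import hddisorient as hdd
from hddisorient.circular import circdiff
from hddisorient.tracking import HeadDirectionSeries
from hddisorient.tuning import TuningCurve, spike_headings

from conftest import make_random_walk_hd


def uniform_sweep_hd(duration=360.0, fs=60.0, speed=60.0):
    """Heading sweeping the circle at constant speed (uniform dwell)."""
    t = np.arange(0, duration, 1 / fs)
    return HeadDirectionSeries(t, np.mod(speed * t, 360.0), np.full(len(t), speed))


class TestTuningCurve:
    def test_spikes_at_one_direction_peak_there(self):
        hd = uniform_sweep_hd()
        # spike whenever the head faces 90 deg
        spike_t = hd.t[np.abs(circdiff(hd.hd, 90.0)) < 0.5]
        tc = hdd.tuning_curve(spike_t, hd)
        stats = hdd.directional_stats(tc)
        assert abs(circdiff(stats.pfd, 90.0)) <= 2.0

    def test_zero_spikes_gives_zero_rate(self):
        hd = uniform_sweep_hd(duration=60.0)
        tc = hdd.tuning_curve(np.array([]), hd)
        assert np.nanmax(tc.rate) == 0.0
        assert hdd.directional_stats(tc).rayleigh_r == 0.0

    def test_dwell_density_integrates_to_one(self, baseline_session, baseline_hd):
        tc = hdd.tuning_curve(baseline_session.spikes[0].t, baseline_hd)
        assert tc.dwell_density.sum() == pytest.approx(1.0, abs=1e-6)
        assert tc.spike_density.sum() == pytest.approx(1.0, abs=1e-6)

    def test_mean_rate_equals_spikes_over_time(self, baseline_session, baseline_hd):
        tc = hdd.tuning_curve(baseline_session.spikes[0].t, baseline_hd)
        mean_rate = np.nansum(tc.rate * tc.dwell_density)
        assert mean_rate == pytest.approx(tc.total_spikes / tc.total_time, rel=1e-6)

    def test_kde_matches_binned_histogram_oracle(self, baseline_session, baseline_hd):
        """The circular-KDE curve should track a 6-deg binned histogram
        estimate of rate within 15% of the peak."""
        st = baseline_session.spikes[0]
        tc = hdd.tuning_curve(st.t, baseline_hd)
        edges = np.arange(0.0, 366.0, 6.0)
        sp_hd = spike_headings(st.t, baseline_hd)
        spike_counts, _ = np.histogram(sp_hd, bins=edges)
        dwell_counts, _ = np.histogram(baseline_hd.hd, bins=edges)
        hist_rate = spike_counts / (dwell_counts / baseline_hd.fs)
        kde_at_centers = tc.rate.reshape(60, 6).mean(axis=1)
        dev = np.abs(kde_at_centers - hist_rate)
        assert dev.max() < 0.15 * np.nanmax(hist_rate)

    def test_narrow_kernel_converges_to_histogram(self, baseline_session, baseline_hd):
        st = baseline_session.spikes[0]
        tc = hdd.tuning_curve(st.t, baseline_hd, kernel_width=0.01)
        edges = np.arange(0.0, 361.0, 1.0)
        sp_hd = spike_headings(st.t, baseline_hd)
        spike_counts, _ = np.histogram(sp_hd, bins=edges)
        dwell_counts, _ = np.histogram(baseline_hd.hd, bins=edges)
        with np.errstate(divide="ignore", invalid="ignore"):
            hist_rate = spike_counts / (dwell_counts / baseline_hd.fs)
        ok = np.isfinite(hist_rate) & np.isfinite(tc.rate) & (dwell_counts > 2)
        assert np.abs(tc.rate[ok] - hist_rate[ok]).max() < 0.2 * np.nanmax(hist_rate[ok])

    def test_empty_window_rejected(self, baseline_hd):
        with pytest.raises(ValueError):
            hdd.tuning_curve(np.array([1.0]), baseline_hd, window=(1e6, 1e6 + 1))


class TestDirectionalStats:
    def test_uniform_rate_has_zero_rayleigh(self):
        centers = np.arange(0.5, 360.5)
        tc = TuningCurve(centers, np.full(360, 7.0), np.full(360, 1 / 360),
                         np.full(360, 1 / 360), 100.0, 700)
        assert hdd.directional_stats(tc).rayleigh_r == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_rate_has_unit_rayleigh(self):
        centers = np.arange(0.5, 360.5)
        rate = np.zeros(360)
        rate[45] = 10.0
        tc = TuningCurve(centers, rate, np.full(360, 1 / 360), rate / rate.sum(),
                         100.0, 1000)
        s = hdd.directional_stats(tc)
        assert s.rayleigh_r == pytest.approx(1.0)
        assert s.pfd == centers[45]

    def test_antipodal_peaks_cancel_and_tie_breaks_low(self):
        centers = np.arange(0.5, 360.5)
        rate = np.zeros(360)
        rate[[10, 190]] = 5.0  # equal peaks 180 deg apart
        tc = TuningCurve(centers, rate, np.full(360, 1 / 360), rate / rate.sum(),
                         100.0, 1000)
        s = hdd.directional_stats(tc)
        assert s.rayleigh_r == pytest.approx(0.0, abs=1e-12)
        assert s.pfd == centers[10]

    def test_rayleigh_invariant_under_rotation(self, baseline_session, baseline_hd):
        st = baseline_session.spikes[0]
        r0 = hdd.directional_stats(hdd.tuning_curve(st.t, baseline_hd)).rayleigh_r
        rotated = HeadDirectionSeries(
            baseline_hd.t, np.mod(baseline_hd.hd + 77.0, 360.0), baseline_hd.ahv
        )
        r1 = hdd.directional_stats(hdd.tuning_curve(st.t, rotated)).rayleigh_r
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestClassifyHdCell:
    def test_tuned_cell_is_classified(self, baseline_session, baseline_hd):
        res = hdd.classify_hd_cell(
            baseline_session.spikes[0].t, baseline_hd, seed=0
        )
        assert res.is_hd_cell is True
        assert res.rayleigh_r > res.shuffle_p95

    def test_untuned_poisson_cell_rarely_classified(self, baseline_hd):
        rng = np.random.default_rng(123)
        duration = baseline_hd.t[-1]
        hits = 0
        for rep in range(20):
            spikes = np.sort(rng.uniform(0.0, duration, size=rng.poisson(10 * duration)))
            res = hdd.classify_hd_cell(spikes, baseline_hd, seed=rep)
            hits += res.is_hd_cell
        assert hits / 20 <= 0.10

    def test_low_peak_rate_fails_rate_criterion(self, baseline_hd):
        proto = hdd.ProtocolSpec.baseline(duration=480.0)
        cell = hdd.CellSpec(preferred_direction=0.0, peak_rate=4.0,
                            background_rate=0.2)
        st = hdd.generate_spikes(
            cell, hdd.generate_tracking(proto, seed=11), proto, seed=44
        )
        res = hdd.classify_hd_cell(st.t, baseline_hd, seed=1)
        assert res.is_hd_cell is False

    def test_short_session_rejected(self):
        hd = make_random_walk_hd(30.0, seed=5)
        with pytest.raises(ValueError):
            hdd.classify_hd_cell(np.array([1.0, 2.0]), hd, seed=0)


class TestWindowedTuning:
    def test_constant_rotation_needs_no_extension(self, headfixed_dark_session,
                                                  headfixed_dark_hd):
        st = headfixed_dark_session.spikes[0]
        res = hdd.windowed_tuning(st.t, headfixed_dark_hd, (30.0, 90.0))
        assert len(res) == 6
        for w in res:
            assert w.coverage_reached
            assert w.t_end - w.t_start == pytest.approx(10.0, abs=0.01)

    def test_immobile_phase_flagged(self, headfixed_dark_session, headfixed_dark_hd):
        st = headfixed_dark_session.spikes[0]
        res = hdd.windowed_tuning(st.t, headfixed_dark_hd, (0.0, 30.0))
        assert all(not w.coverage_reached for w in res)

    def test_phase_shorter_than_window_rejected(self, baseline_hd):
        with pytest.raises(ValueError):
            hdd.windowed_tuning(np.array([]), baseline_hd, (0.0, 5.0))


class TestPerRevolutionTuning:
    def test_returns_first_six_of_many_revolutions(self, headfixed_dark_session,
                                                   headfixed_dark_hd):
        st = headfixed_dark_session.spikes[0]
        revs = hdd.per_revolution_tuning(
            st.t, headfixed_dark_hd, hdd.PhaseBounds(30.0, 90.0, "metadata")
        )
        assert len(revs) == 6
        durations = [r.t_end - r.t_start for r in revs]
        assert np.median(durations) == pytest.approx(360.0 / 186.0, abs=0.05)

    def test_stationary_phase_yields_nothing(self, baseline_hd):
        phases = hdd.PhaseBounds(0.0, 30.0, "metadata")
        hd = make_random_walk_hd(40.0, seed=2, omega_sd=5.0)
        assert hdd.per_revolution_tuning(np.array([]), hd, phases) == []

    def test_imposed_per_revolution_shift_recovered(self):
        """Spike packets planted 5 deg further CW on each revolution of
        a constant CW sweep: successive PFDs should decrease by ~5 deg."""
        fs, speed = 60.0, 180.0
        t = np.arange(0.0, 24.0, 1 / fs)
        heading = np.mod(300.0 - speed * t, 360.0)
        hd = HeadDirectionSeries(t, heading, np.full(len(t), -speed))
        rev = 360.0 / speed
        spikes = []
        for k in range(12):
            target = 100.0 - 5.0 * k
            in_rev = (t >= k * rev) & (t < (k + 1) * rev)
            near = in_rev & (np.abs(circdiff(heading, target)) < 6.0)
            spikes.append(np.repeat(t[near], 5))
        spikes = np.sort(np.concatenate(spikes))
        revs = hdd.per_revolution_tuning(
            spikes, hd, hdd.PhaseBounds(0.0, 24.0, "metadata"), n_revs=12
        )
        pfds = np.array([r.stats.pfd for r in revs])
        steps = circdiff(pfds[1:], pfds[:-1])
        assert np.mean(steps) == pytest.approx(-5.0, abs=1.5)
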