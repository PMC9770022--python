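"""Circular tuning curves, directional statistics, shuffle-based HD-cell
classification, and windowed / per-revolution tuning.

A tuning curve is the ratio of two circular kernel density estimates
over 360 one-degree bins: the density of head directions at spike times
(spike density) and the density of all sampled head directions (dwell
density), scaled so the dwell-weighted mean rate equals total spikes
over total time.  The kernel is von Mises with circular SD 0.1 rad
(kappa = 100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import resultant_vector, unwrap_deg, von_mises_kde, wrap360
from .tracking import HeadDirectionSeries

__all__ = [
    "TuningCurve",
    "DirectionalStats",
    "WindowedResult",
    "RevolutionTuning",
    "tuning_curve",
    "directional_stats",
    "classify_hd_cell",
    "windowed_tuning",
    "per_revolution_tuning",
]

KERNEL_WIDTH_RAD = 0.1
N_BINS = 360
DWELL_EPS = 1e-9  # dwell-density mass below this counts as unsampled


@dataclass
class TuningCurve:
    """360-bin circular firing-rate map.

    ``rate`` is NaN on bins with (essentially) zero dwell.  Densities
    each sum to 1 over the bins (spike density is all-zero for a
    spikeless window).
    """

    bin_centers: np.ndarray
    rate: np.ndarray  # Hz
    dwell_density: np.ndarray
    spike_density: np.ndarray
    total_time: float
    total_spikes: int

    @property
    def sampled(self) -> np.ndarray:
        return np.isfinite(self.rate)


@dataclass
class DirectionalStats:
    """Directionality summary of one tuning curve."""

    rayleigh_r: float
    pfd: float  # degrees, bin centre of the peak
    peak_rate: float  # Hz
    is_hd_cell: bool | None = None
    shuffle_p95: float | None = None


@dataclass
class WindowedResult:
    t_start: float
    t_end: float
    coverage: float
    coverage_reached: bool
    curve: TuningCurve
    stats: DirectionalStats


@dataclass
class RevolutionTuning:
    index: int
    t_start: float
    t_end: float
    curve: TuningCurve
    stats: DirectionalStats


def spike_headings(spike_times, hd: HeadDirectionSeries):
    """Head direction at each spike time, by interpolating the unwrapped
    HD series."""
    uw = unwrap_deg(hd.hd)
    return wrap360(np.interp(spike_times, hd.t, uw))


def tuning_curve(
    spike_times,
    hd: HeadDirectionSeries,
    window=None,
    kernel_width: float = KERNEL_WIDTH_RAD,
) -> TuningCurve:
    """Circular-KDE tuning curve for one cell over an optional window.

    Parameters
    ----------
    spike_times : array-like
        Spike times in seconds (seconds of the same clock as ``hd.t``).
    hd : HeadDirectionSeries
    window : (t0, t1), optional
        Restrict to samples/spikes with t0 <= t < t1.
    kernel_width : float
        Circular SD of the von Mises kernel in radians
        (kappa = 1 / width**2).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if window is not None:
        t0, t1 = window
        m = (hd.t >= t0) & (hd.t < t1)
        sub = HeadDirectionSeries(hd.t[m], hd.hd[m], hd.ahv[m])
        spike_times = spike_times[(spike_times >= t0) & (spike_times < t1)]
    else:
        sub = hd
    if len(sub) < 2:
        raise ValueError("empty or near-empty window")

    kappa = 1.0 / kernel_width**2
    centers, dwell = von_mises_kde(sub.hd, kappa, N_BINS)
    sp_hd = spike_headings(spike_times, sub)
    _, spike_d = von_mises_kde(sp_hd, kappa, N_BINS)

    total_time = len(sub) / sub.fs
    n_spikes = len(spike_times)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(dwell > DWELL_EPS, spike_d / dwell, np.nan) * (
            n_spikes / total_time
        )
    return TuningCurve(centers, rate, dwell, spike_d, total_time, int(n_spikes))


def directional_stats(tc: TuningCurve) -> DirectionalStats:
    """Rayleigh vector length, preferred direction and peak rate of a
    tuning curve.

    The Rayleigh vector is the rate-weighted mean resultant over bin
    centres; the PFD is the bin of maximum rate (ties broken to the
    lowest angle).  A spikeless curve has r = 0 and an undefined (NaN)
    PFD.
    """
    ok = tc.sampled
    if not ok.any():
        raise ValueError("all bins masked; directional statistics undefined")
    rates = tc.rate[ok]
    angles = tc.bin_centers[ok]
    if rates.sum() <= 0:
        return DirectionalStats(0.0, np.nan, 0.0)
    r, _ = resultant_vector(angles, weights=rates)
    i = int(np.nanargmax(np.where(ok, tc.rate, -np.inf)))
    return DirectionalStats(float(r), float(tc.bin_centers[i]), float(np.max(rates)))


def classify_hd_cell(
    spike_times,
    hd: HeadDirectionSeries,
    n_shuffles: int = 100,
    min_shift: float = 20.0,
    shift_step: float = 0.02,
    rate_threshold: float = 5.0,
    seed=None,
) -> DirectionalStats:
    """Shuffle test for directional modulation on a baseline session.

    Each shuffle time-shifts the spike train circularly by
    ``min_shift`` plus a random multiple of ``shift_step`` (shift
    uniform in [20 s, T - 20 s], wrapping at the session end) and
    recomputes the Rayleigh vector.  The cell is classified as an HD
    cell if the observed r exceeds the 95th percentile of the shuffled
    values and its peak rate exceeds ``rate_threshold`` Hz.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    t0, t1 = hd.t[0], hd.t[-1]
    duration = t1 - t0
    if duration < 2 * min_shift:
        raise ValueError("session shorter than twice the minimum shuffle shift")
    rng = np.random.default_rng(seed)

    obs = directional_stats(tuning_curve(spike_times, hd))
    n_steps = int((duration - 2 * min_shift) / shift_step)
    shifts = min_shift + shift_step * rng.integers(0, n_steps + 1, size=n_shuffles)
    r_shuf = np.empty(n_shuffles)
    rel = spike_times - t0
    for i, s in enumerate(shifts):
        shifted = np.sort(np.mod(rel + s, duration)) + t0
        r_shuf[i] = directional_stats(tuning_curve(shifted, hd)).rayleigh_r
    p95 = float(np.percentile(r_shuf, 95))
    is_hd = bool(obs.rayleigh_r > p95 and obs.peak_rate > rate_threshold)
    return DirectionalStats(obs.rayleigh_r, obs.pfd, obs.peak_rate, is_hd, p95)


def _bin_coverage(hd_sub):
    """Fraction of the 360 one-degree bins carrying dwell-density mass
    above ``DWELL_EPS`` (the KDE spreads each sample over the kernel
    width, so a discretely sampled sweep still counts as covering the
    bins it passes through)."""
    if len(hd_sub) == 0:
        return 0.0
    _, density = von_mises_kde(hd_sub, 1.0 / KERNEL_WIDTH_RAD**2, N_BINS)
    return float((density > DWELL_EPS).mean())


def windowed_tuning(
    spike_times,
    hd: HeadDirectionSeries,
    phase,
    window_s: float = 10.0,
    extend_s: float = 2.0,
    coverage: float = 0.90,
):
    """Tile a phase into nonoverlapping windows and compute per-window
    tuning.

    Each ``window_s`` window is extended in ``extend_s`` steps (capped
    at the phase end) until at least ``coverage`` of the directional
    bins are sampled; windows that never reach coverage are emitted
    flagged, with statistics on the available bins.
    """
    t0, t1 = phase
    if t1 - t0 < window_s:
        raise ValueError("phase shorter than one window")
    spike_times = np.asarray(spike_times, dtype=float)
    results = []
    start = t0
    while start + window_s <= t1 + 1e-9:
        end = min(start + window_s, t1)
        while True:
            m = (hd.t >= start) & (hd.t < end)
            cov = _bin_coverage(hd.hd[m])
            if cov >= coverage or end >= t1 - 1e-9:
                break
            end = min(end + extend_s, t1)
        tc = tuning_curve(spike_times, hd, window=(start, end))
        st = directional_stats(tc)
        results.append(WindowedResult(start, end, cov, cov >= coverage, tc, st))
        start += window_s
    return results


def per_revolution_tuning(
    spike_times, hd: HeadDirectionSeries, phases, n_revs: int = 6
):
    """One tuning curve per full 360 deg of cumulative rotation.

    Splits the rotation phase at each complete revolution of the
    unwrapped heading and returns the first ``n_revs`` revolutions (or
    fewer, if the phase contains fewer; the caller can tell from the
    list length).
    """
    m = (hd.t >= phases.rotation_start) & (hd.t <= phases.rotation_end)
    if m.sum() < 2:
        return []
    t_sub = hd.t[m]
    uw = unwrap_deg(hd.hd[m])
    cum = np.abs(uw - uw[0])
    n_available = int(cum[-1] // 360.0)
    spike_times = np.asarray(spike_times, dtype=float)
    out = []
    for k in range(min(n_revs, n_available)):
        i0 = int(np.searchsorted(cum, 360.0 * k))
        i1 = int(np.searchsorted(cum, 360.0 * (k + 1)))
        w = (float(t_sub[i0]), float(t_sub[min(i1, len(t_sub) - 1)]))
        tc = tuning_curve(spike_times, hd, window=w)
        out.append(RevolutionTuning(k, w[0], w[1], tc, directional_stats(tc)))
    return out
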