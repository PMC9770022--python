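"""Burst and interspike-interval analyses, and the postrotational
velocity-storage time constant.

The burst index measures how far a cell's 1-s spike counts sit from its
session mean rate; ISI statistics are restricted to epochs when the
animal faces the cell's preferred direction; spike bursts are peaks of
a kernel-smoothed instantaneous rate; and the time constant converts
the slowing of postrotational interburst intervals into the decay time
of the stored vestibular velocity signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .circular import circdiff, unwrap_deg
from .tracking import HeadDirectionSeries, PhaseBounds

__all__ = [
    "BurstSeries",
    "BurstIndexResult",
    "ISIStats",
    "TimeConstantFit",
    "burst_index",
    "isi_stats",
    "time_after_revolutions",
    "rate_match",
    "detect_bursts",
    "fit_time_constant",
    "mean_time_constant",
    "decay_threshold",
]


@dataclass
class BurstSeries:
    """Detected burst peak times and derived rotation-speed estimates.

    ``speed_estimates`` converts each interburst interval to the
    rotation speed it would correspond to if the internal heading were
    sweeping a full circle per interval: speed = 360 / interval.
    """

    peak_times: np.ndarray  # s, strictly increasing
    heights: np.ndarray = None  # smoothed-count units at each peak

    def __post_init__(self):
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if len(self.peak_times) > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")

    @property
    def interburst_intervals(self) -> np.ndarray:
        return np.diff(self.peak_times)

    @property
    def speed_estimates(self) -> np.ndarray:
        return 360.0 / self.interburst_intervals

    def __len__(self):
        return len(self.peak_times)


@dataclass
class BurstIndexResult:
    value: float  # in [0, 1]
    mean_rate: float  # spikes per bin (= Hz for 1-s bins)
    n_bins: int
    degenerate: bool = False


@dataclass
class ISIStats:
    """Interspike intervals within PFD-facing epochs."""

    isis: np.ndarray  # s
    mean_isi: float
    frac_short: float  # fraction of ISIs < 25 ms
    pfd_rate: float  # spikes per second of PFD-facing time
    n_spikes: int
    total_epoch_time: float
    excluded: bool  # fewer than the minimum number of ISIs


@dataclass
class TimeConstantFit:
    """Exponential fit speed = a * exp(b * rank) over the first ranked
    interburst intervals of one cell, and the derived decay time."""

    tau: float  # s; <= 0 marks a non-decaying fit
    a: float
    b: float
    n_points: int
    excluded: bool = False  # excluded from the condition mean


def burst_index(
    spike_times,
    session_bounds,
    bin_s: float = 1.0,
    hi: float = 1.75,
    lo: float = 0.25,
) -> BurstIndexResult:
    """Fraction of 1-s bins whose spike count is far above (> hi * R) or
    far below (< lo * R) the session mean rate R.

    0 means firing stays near the mean rate throughout; 1 means the
    cell is either silent or firing near its maximum in every bin
    (all-or-nothing bursting).  Bin phase is anchored at the session
    start.
    """
    t0, t1 = session_bounds
    if t1 - t0 < 2 * bin_s:
        raise ValueError("session must span at least two bins")
    spike_times = np.asarray(spike_times, dtype=float)
    n_bins = int((t1 - t0) // bin_s)
    edges = t0 + bin_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(spike_times, bins=edges)
    R = float(counts.mean())
    if R == 0.0:
        return BurstIndexResult(0.0, 0.0, n_bins, degenerate=True)
    value = float(((counts > hi * R).sum() + (counts < lo * R).sum()) / n_bins)
    return BurstIndexResult(value, R, n_bins)


def _facing_epochs(hd: HeadDirectionSeries, pfd, half_width):
    """Contiguous [t_start, t_end) intervals during which the head is
    within +/- half_width of the PFD."""
    facing = np.abs(circdiff(hd.hd, pfd)) <= half_width
    if not facing.any():
        return []
    d = np.diff(facing.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if facing[0]:
        starts.insert(0, 0)
    if facing[-1]:
        ends.append(len(facing))
    dt = 1.0 / hd.fs
    return [(hd.t[i0], hd.t[i1 - 1] + dt) for i0, i1 in zip(starts, ends)]


def time_after_revolutions(
    hd: HeadDirectionSeries, phases: PhaseBounds, n_revs: int = 6
) -> float:
    """Session time at which the n-th full revolution of the rotation
    phase completes (the phase end, if fewer revolutions exist)."""
    m = (hd.t >= phases.rotation_start) & (hd.t <= phases.rotation_end)
    uw = unwrap_deg(hd.hd[m])
    cum = np.abs(uw - uw[0])
    i = np.searchsorted(cum, 360.0 * n_revs)
    if i >= m.sum():
        return phases.rotation_end
    return float(hd.t[m][i])


def isi_stats(
    spike_times,
    hd: HeadDirectionSeries,
    pfd: float,
    half_width: float = 30.0,
    min_isis: int = 10,
    exclude_until: float | None = None,
    short_isi_s: float = 0.025,
) -> ISIStats:
    """ISI statistics restricted to PFD-facing epochs.

    ISIs are computed within, never across, contiguous epochs during
    which the head is within +/- ``half_width`` degrees of ``pfd``.
    Spikes before ``exclude_until`` (e.g. the end of the sixth
    revolution, per :func:`time_after_revolutions`) are discarded.
    Cells with fewer than ``min_isis`` ISIs are flagged ``excluded``.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if exclude_until is not None:
        spike_times = spike_times[spike_times >= exclude_until]
    epochs = _facing_epochs(hd, pfd, half_width)
    if exclude_until is not None:
        epochs = [
            (max(a, exclude_until), b) for a, b in epochs if b > exclude_until
        ]
    isis = []
    n_spikes = 0
    total_time = 0.0
    for a, b in epochs:
        total_time += b - a
        s = spike_times[(spike_times >= a) & (spike_times < b)]
        n_spikes += len(s)
        if len(s) >= 2:
            isis.append(np.diff(s))
    isis = np.concatenate(isis) if isis else np.empty(0)
    mean_isi = float(isis.mean()) if len(isis) else np.nan
    frac = float((isis < short_isi_s).mean()) if len(isis) else np.nan
    rate = n_spikes / total_time if total_time > 0 else np.nan
    return ISIStats(
        isis, mean_isi, frac, float(rate), n_spikes, total_time,
        excluded=len(isis) < min_isis,
    )


def rate_match(group, baseline, max_dist: float = 1.0):
    """Match each experimental cell to the baseline cell with the
    nearest PFD firing rate (with replacement, within +/- ``max_dist``
    Hz); unmatched cells are dropped.

    Parameters are lists of :class:`ISIStats`.  Returns a list of
    (experimental, matched-baseline) pairs.
    """
    if not group or not baseline:
        raise ValueError("both groups must be non-empty")
    base_rates = np.array([b.pfd_rate for b in baseline])
    pairs = []
    for g in group:
        j = int(np.argmin(np.abs(base_rates - g.pfd_rate)))
        if abs(base_rates[j] - g.pfd_rate) <= max_dist:
            pairs.append((g, baseline[j]))
    return pairs


def detect_bursts(
    spike_times,
    window,
    bin_s: float = 0.02,
    bandwidth_bins: float = 10.0,
    min_height: float = 0.25,
    min_prominence: float = 0.25,
    min_separation_s: float = 0.05,
) -> BurstSeries:
    """Peaks of the kernel-smoothed instantaneous rate.

    Spike counts in ``bin_s`` bins are smoothed with a Gaussian of
    ``bandwidth_bins`` bins; peaks must clear ``min_height`` and
    ``min_prominence`` (both in smoothed-count units, i.e. spikes per
    bin mass) and be separated by more than ``min_separation_s``.
    """
    t0, t1 = window
    if t1 - t0 < 1.0:
        raise ValueError("window must span at least 1 s")
    spike_times = np.asarray(spike_times, dtype=float)
    edges = np.arange(t0, t1 + bin_s / 2, bin_s)
    counts, _ = np.histogram(spike_times, bins=edges)
    smoothed = gaussian_filter1d(counts.astype(float), bandwidth_bins)
    # smallest bin count whose time gap exceeds the minimum separation
    distance = max(1, int(np.floor(min_separation_s / bin_s)) + 1)
    idx, props = find_peaks(
        smoothed, height=min_height, prominence=min_prominence, distance=distance
    )
    times = t0 + (idx + 0.5) * bin_s
    return BurstSeries(times, props.get("peak_heights", np.empty(0)))


def decay_threshold(initial_speed: float) -> float:
    """Speed at which an exponential decay from ``initial_speed`` has
    fallen to 1/e (36.79%) of its starting value (deg/s)."""
    return initial_speed / np.e


def fit_time_constant(
    intervals_per_session,
    rotation_period: float,
    n_intervals: int = 4,
    start=(100.0, 0.25),
) -> TimeConstantFit | None:
    """Velocity-storage decay time for one cell from its postrotational
    interburst intervals.

    Each session contributes its first ``n_intervals`` interburst
    intervals, converted to speeds (360 / interval) and ranked; one
    exponential speed = a * exp(b * rank) is fitted per cell over all
    sessions combined.  tau is the elapsed time at which the fitted
    curve reaches 1/e of the session's rotation speed
    (360 / rotation_period); ranks convert to seconds through the
    fitted interval sequence, the speed of interval k being the
    internal velocity at the interval's start (elapsed time before
    rank k is the cumulative sum of the preceding fitted intervals).

    Returns None when fewer than two intervals exist.  A non-decaying
    fit (b >= 0) yields tau <= 0 and ``excluded=True``.
    """
    ranks, speeds = [], []
    for iv in intervals_per_session:
        iv = np.asarray(iv, dtype=float)[:n_intervals]
        iv = iv[iv > 0]
        ranks.extend(range(1, len(iv) + 1))
        speeds.extend(360.0 / iv)
    if len(speeds) < 2:
        return None
    ranks = np.asarray(ranks, dtype=float)
    speeds = np.asarray(speeds, dtype=float)

    def model(x, a, b):
        return a * np.exp(b * x)

    try:
        (a, b), _ = curve_fit(model, ranks, speeds, p0=start, maxfev=20000)
    except RuntimeError:
        return None

    threshold = decay_threshold(360.0 / rotation_period)
    if b == 0.0 or a <= 0:
        return TimeConstantFit(-np.inf, float(a), float(b), len(speeds), True)
    x_star = np.log(threshold / a) / b

    kk = np.arange(1.0, max(np.ceil(x_star), np.max(ranks)) + 1)
    fitted_iv = 360.0 / model(kk, a, b)
    cum_before = np.concatenate([[0.0], np.cumsum(fitted_iv)[:-1]])
    if x_star < 1.0:
        tau = (x_star - 1.0) * fitted_iv[0]
    else:
        tau = float(np.interp(x_star, kk, cum_before))
    excluded = b >= 0 or tau <= 0
    return TimeConstantFit(float(tau), float(a), float(b), len(speeds), excluded)


def mean_time_constant(fits) -> float:
    """Condition-level time constant: the mean over cells with a valid,
    decaying fit (non-decaying cells are excluded)."""
    taus = [f.tau for f in fits if f is not None and not f.excluded and f.tau > 0]
    if not taus:
        return np.nan
    return float(np.mean(taus))
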