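"""Circular-linear regression of per-revolution preferred directions,
and spectrogram analysis of postrotational bursting.

The regression quantifies how fast a cell's preferred direction slides
during constant rotation (an angular-velocity underestimation shows up
as a slope in the rotation direction).  The spectrogram tracks the
frequency of postrotational spike bursts relative to the rotation
frequency; a velocity-storage signal appears as a ridge near 0 offset
that decays over the recovery period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize_scalar
from scipy.signal import spectrogram as _spectrogram
from scipy.signal.windows import hann
from scipy.stats import ttest_1samp

__all__ = [
    "DriftFit",
    "Spectrogram",
    "drift_regression",
    "slopes_t_test",
    "burst_spectrogram",
]

RATE_BIN_S = 0.02  # 50 Hz instantaneous-rate vector
RATE_BANDWIDTH_S = 0.04


@dataclass
class DriftFit:
    """Circular-linear fit pfd(t) ~ intercept + slope * t."""

    slope: float  # deg/s, CCW-positive
    intercept: float  # deg
    resultant: float  # mean resultant length of residuals at the fit
    rotation_direction: str | None = None


@dataclass
class Spectrogram:
    """Column-z-scored PSD spectrogram of an instantaneous-rate vector.

    ``freq_offsets`` is Hz relative to the rotation frequency;
    ``power_z`` is z-scored within each time column (over the full
    frequency axis, before band restriction); ``peak_freq_curve`` is
    the frequency offset of the strongest power within ``band`` of 0
    for each time bin.
    """

    freq_offsets: np.ndarray
    times: np.ndarray  # s from window start
    time_fraction: np.ndarray  # fraction of the window duration
    power_z: np.ndarray  # (freq, time)
    power_raw: np.ndarray  # PSD before z-scoring
    peak_freq_curve: np.ndarray
    band: float


def _resultant_of_residuals(pfds_rad, times, slope_deg_s):
    resid = pfds_rad - np.radians(slope_deg_s) * times
    return np.hypot(np.cos(resid).sum(), np.sin(resid).sum()) / len(resid)


def drift_regression(
    pfds,
    times,
    direction: str | None = None,
    slope_bounds=None,
    n_grid: int = 4001,
) -> DriftFit:
    """Circular-linear regression of preferred directions on time.

    Finds the slope maximising the mean resultant length of the
    residuals (pfd - slope * t), which handles wrapping of the 0/360
    boundary that defeats ordinary least squares.  The search scans
    ``n_grid`` candidate slopes over ``slope_bounds`` (default: +/- 3
    revolutions per median revolution time) and refines the best
    candidate with bounded scalar minimisation.

    Parameters
    ----------
    pfds : array-like
        Per-revolution preferred directions, degrees.
    times : array-like
        Times of the revolutions, seconds (e.g. revolution midpoints).
    direction : {"CW", "CCW"}, optional
        Annotates the fit; positive slopes mean CCW drift.
    """
    pfds = np.asarray(pfds, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(pfds) < 3:
        raise ValueError("need at least 3 preferred directions to fit a slope")
    if slope_bounds is None:
        # slopes separated by 360/dt are indistinguishable on (near-)
        # regularly sampled angles, so the identifiable range is half
        # the alias spacing around zero
        rev_t = float(np.median(np.diff(np.sort(times))))
        s_max = 0.5 * 360.0 / max(rev_t, 1e-9)
        slope_bounds = (-s_max, s_max)

    t = times - times.mean()
    rad = np.radians(pfds)
    grid = np.linspace(slope_bounds[0], slope_bounds[1], n_grid)
    rr = np.array([_resultant_of_residuals(rad, t, s) for s in grid])
    near = np.flatnonzero(rr >= rr.max() - 1e-9)
    i = int(near[np.argmin(np.abs(grid[near]))])  # ties -> smallest |slope|
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda s: -_resultant_of_residuals(rad, t, s),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    slope = float(res.x)
    resid = rad - np.radians(slope) * t
    mean_resid = np.degrees(np.arctan2(np.sin(resid).sum(), np.cos(resid).sum()))
    intercept = float(np.mod(mean_resid - slope * times.mean(), 360.0))
    return DriftFit(slope, intercept, float(-res.fun), direction)


def slopes_t_test(slopes, direction: str):
    """One-sided one-sample t test of regression slopes against zero,
    in the direction the rotation predicts (negative for CW, positive
    for CCW).  Returns (t, p)."""
    alternative = "less" if direction == "CW" else "greater"
    res = ttest_1samp(np.asarray(slopes, dtype=float), 0.0, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def burst_spectrogram(
    spike_times,
    window,
    rotation_freq: float,
    band: float = 0.2,
    nperseg: int = 512,
    overlap: float = 0.9,
    nfft: int = 1024,
) -> Spectrogram:
    """Frequency-time PSD spectrogram of a cell's instantaneous rate.

    The rate vector is a kernel-smoothed density of spike times (20-ms
    bins, 40-ms Gaussian bandwidth, i.e. 50 Hz sampling, so a
    512-sample window spans 10.24 s).  Hanning windows with 90% overlap
    and ``nfft``-point frequency resolution; the frequency axis is
    shifted so 0 corresponds to the rotation frequency and each time
    column is z-scored over the full frequency axis.
    """
    t0, t1 = window
    fs = 1.0 / RATE_BIN_S
    edges = np.arange(t0, t1 + RATE_BIN_S / 2, RATE_BIN_S)
    if len(edges) - 1 < nperseg:
        raise ValueError("window shorter than one spectrogram segment")
    counts, _ = np.histogram(np.asarray(spike_times, dtype=float), bins=edges)
    rate = gaussian_filter1d(counts.astype(float), RATE_BANDWIDTH_S / RATE_BIN_S) / RATE_BIN_S

    freqs, times, sxx = _spectrogram(
        rate,
        fs=fs,
        window=hann(nperseg),
        nperseg=nperseg,
        noverlap=int(overlap * nperseg),
        nfft=nfft,
        scaling="density",
        mode="psd",
    )
    mu = sxx.mean(axis=0, keepdims=True)
    sd = sxx.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sxx - mu) / sd

    offsets = freqs - rotation_freq
    in_band = np.abs(offsets) <= band
    if not in_band.any():
        raise ValueError("no frequency bins within the band of the rotation frequency")
    band_offsets = offsets[in_band]
    peak_curve = band_offsets[np.argmax(z[in_band, :], axis=0)]
    return Spectrogram(
        offsets, times, times / (t1 - t0), z, sxx, peak_curve, band
    )
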