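"""HD x AHV bivariate maps and baseline-conditioned spike prediction.

Tests whether firing-rate changes in a rotation session are explained by
its angular-head-velocity sampling: a firing-probability map conditioned
on (HD, AHV) is estimated from the first visual baseline, multiplied by
the session's own (HD, AHV) dwell map to predict spiking, and compared
with observed spiking through two bounded indices.

Grid: 60 HD bins of 6 deg over [0, 360) by 100 AHV bins of 6 deg/s over
[-300, 300].  Dwell and spike maps are smoothed separately with a
truncated 3x3 Gaussian (sigma 1.5 bins, renormalised), then divided;
bins with < 0.1 s of (smoothed) dwell are unvisited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .circular import unwrap_deg, wrap360
from .tracking import HeadDirectionSeries

__all__ = [
    "AHVMap",
    "PredictedSpikes",
    "build_ahv_map",
    "predict_spikes",
    "spike_rate_index",
    "peak_rate_index",
    "hd_tuning_from_map",
]

HD_EDGES = np.linspace(0.0, 360.0, 61)
AHV_EDGES = np.linspace(-300.0, 300.0, 101)
OCCUPANCY_MIN_S = 0.1
SMOOTH_SIGMA_BINS = 1.5


@dataclass
class AHVMap:
    """Bivariate (HD, AHV) occupancy/spiking map.

    Arrays are (60 HD bins, 100 AHV bins).  ``dwell`` is smoothed
    seconds, ``spikes`` smoothed counts, ``prob`` spikes per dwell
    sample (defined on visited bins only, NaN elsewhere).
    """

    dwell: np.ndarray  # s
    spikes: np.ndarray  # counts
    prob: np.ndarray
    visited: np.ndarray
    dt: float  # position sampling interval, s
    n_dropped: int  # samples outside the AHV range

    @property
    def rate(self) -> np.ndarray:
        """Firing rate in Hz (prob / sampling interval)."""
        return self.prob / self.dt


@dataclass
class PredictedSpikes:
    """Spike map predicted from a baseline probability map and a
    session dwell map, with the joint visited mask."""

    spikes: np.ndarray
    dwell: np.ndarray  # the session dwell, jointly masked (s)
    visited: np.ndarray
    dt: float


def _gauss3_kernel(sigma=SMOOTH_SIGMA_BINS):
    k = np.exp(-0.5 * (np.array([-1.0, 0.0, 1.0]) / sigma) ** 2)
    return k / k.sum()


def _smooth(map2d):
    """Separable truncated-Gaussian smoothing: circular over HD (axis
    0), edge-replicated over AHV (axis 1); unit-sum kernel."""
    k = _gauss3_kernel()
    out = correlate1d(map2d, k, axis=0, mode="wrap")
    return correlate1d(out, k, axis=1, mode="nearest")


def build_ahv_map(spike_times, hd: HeadDirectionSeries) -> AHVMap:
    """Bivariate dwell/spike/probability maps for one cell.

    Samples (and spikes) with |AHV| > 300 deg/s are dropped and counted
    in ``n_dropped``.  The unvisited mask (< 0.1 s dwell) is applied
    after smoothing.
    """
    dt = 1.0 / hd.fs
    ok = np.abs(hd.ahv) <= AHV_EDGES[-1]
    n_dropped = int((~ok).sum())

    dwell_counts, _, _ = np.histogram2d(
        wrap360(hd.hd[ok]), hd.ahv[ok], bins=[HD_EDGES, AHV_EDGES]
    )

    spike_times = np.asarray(spike_times, dtype=float)
    uw = unwrap_deg(hd.hd)
    sp_hd = wrap360(np.interp(spike_times, hd.t, uw))
    sp_ahv = np.interp(spike_times, hd.t, hd.ahv)
    sok = np.abs(sp_ahv) <= AHV_EDGES[-1]
    n_dropped += int((~sok).sum())
    spike_counts, _, _ = np.histogram2d(
        sp_hd[sok], sp_ahv[sok], bins=[HD_EDGES, AHV_EDGES]
    )

    dwell_s = _smooth(dwell_counts) * dt
    spikes_s = _smooth(spike_counts)
    visited = dwell_s >= OCCUPANCY_MIN_S
    with np.errstate(divide="ignore", invalid="ignore"):
        prob = np.where(visited, spikes_s / (dwell_s / dt), np.nan)
    return AHVMap(dwell_s, spikes_s, prob, visited, dt, n_dropped)


def predict_spikes(baseline: AHVMap, session: AHVMap) -> PredictedSpikes:
    """Predicted spike map: session dwell times baseline firing
    probability, elementwise; bins unvisited in either map are
    unvisited in both."""
    if baseline.dwell.shape != session.dwell.shape:
        raise ValueError("bin grids do not match")
    joint = baseline.visited & session.visited
    pred = np.where(joint, (session.dwell / session.dt) * baseline.prob, np.nan)
    dwell = np.where(joint, session.dwell, np.nan)
    return PredictedSpikes(pred, dwell, joint, session.dt)


def spike_rate_index(actual: AHVMap, predicted: PredictedSpikes) -> float:
    """(observed - predicted) / (observed + predicted) total spikes on
    jointly visited bins; 0 means the cell fired at exactly the rate
    expected from its baseline (HD, AHV) modulation."""
    joint = actual.visited & predicted.visited
    a = float(actual.spikes[joint].sum())
    b = float(np.nansum(predicted.spikes[joint]))
    if a + b == 0:
        raise ValueError("no spikes observed or predicted on the joint mask")
    return (a - b) / (a + b)


def hd_tuning_from_map(spikes2d, dwell2d, mask) -> np.ndarray:
    """Collapse a bivariate spike map to a 60-bin HD tuning curve (Hz):
    per-HD-bin spike sum over AHV divided by dwell-time sum, restricted
    to ``mask``."""
    sp = np.where(mask, spikes2d, 0.0).sum(axis=1)
    dw = np.where(mask, dwell2d, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dw > 0, sp / dw, np.nan)


def peak_rate_index(actual: AHVMap, predicted: PredictedSpikes) -> float:
    """Index on the peaks of the column-summed (HD) tuning curves of the
    observed and predicted spike maps."""
    joint = actual.visited & predicted.visited
    tc_a = hd_tuning_from_map(actual.spikes, actual.dwell, joint)
    tc_p = hd_tuning_from_map(predicted.spikes, predicted.dwell, joint)
    a = float(np.nanmax(tc_a))
    b = float(np.nanmax(tc_p))
    if a + b == 0:
        raise ValueError("both tuning curves are identically zero")
    return (a - b) / (a + b)
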