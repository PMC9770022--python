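"""Synthetic head-direction cell sessions.

Generates two-LED tracking and spike trains with the statistical
structure the downstream analyses assume: von Mises HD tuning, darkness
drift of the preferred direction, a cumulative underestimation of
angular velocity during head-fixed rotation, loss of directional gain
("disorientation") during dark rotation, and exponentially slowing
postrotational bursting driven by a decaying velocity-storage signal.

Conventions: arena-centre origin, centimetres; angles in degrees,
CCW-positive, 0 deg along +x.  Tracking is sampled at 60 Hz with the
two LEDs 10 cm apart along the heading axis.  Spiking is an
inhomogeneous Poisson process thinned on a 1 ms grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .circular import unwrap_deg, wrap360
from .tracking import TrackingSeries

__all__ = [
    "CellSpec",
    "ProtocolSpec",
    "SpikeTrain",
    "SyntheticSession",
    "generate_tracking",
    "generate_spikes",
    "generate_session",
]

LED_SEPARATION_CM = 10.0
FS_TRACKING = 60.0
DT_SPIKES = 1e-3


@dataclass
class CellSpec:
    """Ground-truth tuning of one simulated HD cell.

    Parameters
    ----------
    preferred_direction : float
        PFD in degrees, [0, 360).
    peak_rate : float
        In-PFD firing rate, Hz.  Recorded HD cells span roughly
        8-80 Hz (median ~35 Hz).
    background_rate : float
        Out-of-field rate, Hz.
    tuning_concentration : float
        von Mises concentration kappa (dimensionless); kappa = 4 gives a
        tuning width typical of anterodorsal thalamic HD cells.
    ahv_gain : float
        Fractional rate increase per 100 deg/s of |AHV| (0 = no AHV
        modulation).
    cell_id : str
    """

    preferred_direction: float = 0.0
    peak_rate: float = 35.0
    background_rate: float = 1.0
    tuning_concentration: float = 4.0
    ahv_gain: float = 0.0
    cell_id: str = "cell0"

    def __post_init__(self):
        if not np.isfinite(self.tuning_concentration) or self.tuning_concentration <= 0:
            raise ValueError("tuning_concentration must be finite and > 0")
        if self.peak_rate <= self.background_rate:
            raise ValueError("peak_rate must exceed background_rate")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        self.preferred_direction = float(wrap360(self.preferred_direction))


@dataclass
class ProtocolSpec:
    """One session's behavioural protocol and internal-model parameters.

    ``durations`` are seconds of (pre, rotation, recovery).  Baseline
    sessions have ``nominal_speed`` 0 and no rotation/recovery phases.

    ``drift_rate_dark`` scales a Brownian rotation of the cell's
    internal reference in darkness (deg per sqrt-minute; recorded HD
    cells drift ~1.5 deg/min in darkness).  ``underestimation`` is the
    deg/s by which the internal heading update lags true rotation while
    head-fixed, accumulating a PFD shift in the rotation direction.
    ``storage_time_constant`` (s) sets the exponential slow-down of
    postrotational bursting after dark head-fixed rotation.
    ``disorientation_tau`` (s) is the time constant with which
    directional gain collapses during disorienting (dark, or fast
    unrestrained) rotation and recovers afterwards; None disables it.
    ``postrotation_bias`` (deg/s) is an initial head-turn bias in the
    rotation direction during free recovery, decaying with the storage
    time constant (the somatogyral after-effect on behaviour).
    """

    protocol: str = "baseline"  # baseline | bidirectional | unidirectional_free | head_fixed
    illumination: str = "light"  # light | dark
    nominal_speed: float = 0.0  # deg/s
    rotation_direction: str = "CCW"  # CW | CCW | alternating
    durations: tuple = (480.0, 0.0, 0.0)  # (pre, rotation, recovery) s
    drift_rate_dark: float = 1.5  # deg/min Brownian scale
    underestimation: float = 4.5  # deg/s, head-fixed rotation only
    storage_time_constant: float = 3.8  # s
    disorientation_tau: float | None = 20.0  # s
    postrotation_bias: float = 0.0  # deg/s
    seed: int | None = None

    _PROTOCOLS = ("baseline", "bidirectional", "unidirectional_free", "head_fixed")

    def __post_init__(self):
        if self.protocol not in self._PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.illumination not in ("light", "dark"):
            raise ValueError("illumination must be 'light' or 'dark'")
        if any(d < 0 for d in self.durations) or len(self.durations) != 3:
            raise ValueError("durations must be three non-negative values")
        if (self.nominal_speed == 0) != (self.protocol == "baseline"):
            raise ValueError("nominal_speed must be 0 iff protocol is baseline")
        if self.nominal_speed < 0:
            raise ValueError("nominal_speed must be >= 0 (sign comes from direction)")

    # --- convenience constructors for the three experiment designs ---
    @classmethod
    def baseline(cls, duration=480.0, illumination="light", **kw):
        return cls(protocol="baseline", illumination=illumination,
                   durations=(duration, 0.0, 0.0), **kw)

    @classmethod
    def bidirectional(cls, speed=111.0, illumination="dark",
                      durations=(60.0, 120.0, 0.0), **kw):
        """Unrestrained back-and-forth rotation (Experiment-1 style)."""
        return cls(protocol="bidirectional", illumination=illumination,
                   nominal_speed=speed, rotation_direction="alternating",
                   durations=durations, **kw)

    @classmethod
    def unidirectional_free(cls, speed=260.0, illumination="dark",
                            direction="CCW", durations=(60.0, 60.0, 120.0), **kw):
        """Unrestrained constant-speed rotation (Experiment-2 style)."""
        return cls(protocol="unidirectional_free", illumination=illumination,
                   nominal_speed=speed, rotation_direction=direction,
                   durations=durations, **kw)

    @classmethod
    def head_fixed(cls, speed=186.0, illumination="dark",
                   direction="CCW", durations=(30.0, 60.0, 120.0), **kw):
        """Head-fixed motorised rotation (Experiment-3 style)."""
        return cls(protocol="head_fixed", illumination=illumination,
                   nominal_speed=speed, rotation_direction=direction,
                   durations=durations, **kw)

    @property
    def phase_times(self):
        """(t_pre_end, t_rot_end, t_session_end) in seconds."""
        pre, rot, rec = self.durations
        return pre, pre + rot, pre + rot + rec

    @property
    def direction_sign(self) -> float:
        return -1.0 if self.rotation_direction == "CW" else 1.0


@dataclass
class SpikeTrain:
    """One cell's spike times (seconds) within one session."""

    t: np.ndarray
    t_start: float
    t_stop: float
    cell_id: str = "cell0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if len(self.t) and (
            np.any(np.diff(self.t) < 0)
            or self.t[0] < self.t_start
            or self.t[-1] > self.t_stop
        ):
            raise ValueError("spikes must be sorted and within session bounds")

    def __len__(self):
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start


@dataclass
class SyntheticSession:
    """Tracking plus spike trains plus the ground truth that made them."""

    tracking: TrackingSeries
    spikes: list
    cell_specs: list
    protocol: ProtocolSpec


def _foraging_heading(n, dt, rng, omega_sd=90.0, tau=0.35):
    """Ergodic random-walk heading: Ornstein-Uhlenbeck angular velocity
    (stationary SD ``omega_sd`` deg/s, correlation time ``tau`` s),
    integrated to heading.  Any ergodic walk works; this one covers the
    circle well within a few minutes at rat-like head speeds."""
    a = np.exp(-dt / tau)
    noise_sd = omega_sd * np.sqrt(1.0 - a * a)
    omega = np.empty(n)
    omega[0] = rng.normal(0.0, omega_sd)
    eps = rng.normal(0.0, noise_sd, size=n - 1)
    for i in range(1, n):
        omega[i] = a * omega[i - 1] + eps[i - 1]
    return omega


def _foraging_position(n, dt, rng, radius=40.0, speed_sd=8.0, tau=1.0):
    """2-D OU random walk reflected at the arena wall (cm)."""
    a = np.exp(-dt / tau)
    noise_sd = speed_sd * np.sqrt(1.0 - a * a)
    v = rng.normal(0.0, speed_sd, size=2)
    p = np.zeros((n, 2))
    p[0] = rng.uniform(-radius / 2, radius / 2, size=2)
    for i in range(1, n):
        v = a * v + rng.normal(0.0, noise_sd, size=2)
        q = p[i - 1] + v * dt
        r = np.hypot(*q)
        if r > radius:
            q *= (2 * radius - r) / r  # reflect
            v = -v
        p[i] = q
    return p


def generate_tracking(proto: ProtocolSpec, seed=None) -> TrackingSeries:
    """Simulate 60 Hz two-LED tracking for one session.

    Heading follows the protocol: random-walk foraging in baseline and
    free pre/recovery phases, constant angular velocity for
    unidirectional and head-fixed rotation, and alternating-direction
    blocks of 5-10 s for bidirectional rotation.  Head-fixed animals are
    stationary outside the rotation phase.
    """
    if seed is None:
        seed = proto.seed
    rng = np.random.default_rng(seed)
    dt = 1.0 / FS_TRACKING
    t_pre, t_rot, t_end = proto.phase_times
    t = np.arange(0.0, t_end, dt)
    n = len(t)
    if n < 2:
        raise ValueError("session too short")

    omega = np.zeros(n)
    in_pre = t < t_pre
    in_rot = (t >= t_pre) & (t < t_rot)
    in_rec = t >= t_rot

    free = proto.protocol in ("baseline", "bidirectional", "unidirectional_free")
    if free:
        forage = _foraging_heading(n, dt, rng)
        omega[in_pre] = forage[in_pre]
        omega[in_rec] = forage[in_rec]
        if proto.postrotation_bias != 0.0 and in_rec.any():
            tr = t[in_rec] - t_rot
            omega[in_rec] += (
                proto.direction_sign
                * proto.postrotation_bias
                * np.exp(-tr / proto.storage_time_constant)
            )

    if in_rot.any():
        if proto.protocol == "bidirectional":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            tt = t_pre
            block = np.zeros(n)
            while tt < t_rot:
                dur = rng.uniform(5.0, 10.0)
                block[(t >= tt) & (t < min(tt + dur, t_rot))] = sign
                sign = -sign
                tt += dur
            omega[in_rot] = block[in_rot] * proto.nominal_speed
        else:
            omega[in_rot] = proto.direction_sign * proto.nominal_speed

    hd0 = rng.uniform(0.0, 360.0)
    heading = hd0 + np.concatenate([[0.0], np.cumsum(omega[:-1]) * dt])

    if free:
        pos = _foraging_position(n, dt, rng)
        if in_rot.any():
            # animal stays put on the platform while it rotates
            i0 = int(np.flatnonzero(in_rot)[0])
            pos[in_rot] = pos[max(i0 - 1, 0)]
    else:
        pos = np.zeros((n, 2))

    u = np.column_stack([np.cos(np.radians(heading)), np.sin(np.radians(heading))])
    half = LED_SEPARATION_CM / 2.0
    red = pos + half * u
    green = pos - half * u

    meta = {
        "protocol": asdict(proto),
        "phase_times": (t_pre, t_rot, t_end),
        "heading_truth_start": hd0,
    }
    return TrackingSeries(t, red, green, np.ones(n, bool), meta)


def _true_heading(tracking: TrackingSeries) -> np.ndarray:
    vec = tracking.red_xy - tracking.green_xy
    return wrap360(np.degrees(np.arctan2(vec[:, 1], vec[:, 0])))


def _tuning_gain_trace(tg, proto: ProtocolSpec):
    """Directional-gain trace g(t) in [0, 1]: collapses with time
    constant ``disorientation_tau`` during disorienting rotation and
    recovers with the same time constant afterwards.

    The asymptotic loss scales linearly with rotation speed (saturating
    at 300 deg/s) and is three times stronger in darkness than with
    visual cues available; light head-fixed rotation is spared (the
    gaze can fixate).
    """
    if proto.disorientation_tau is None or proto.protocol == "baseline":
        return np.ones_like(tg)
    strength = (1.0 if proto.illumination == "dark" else 1.0 / 3.0) * min(
        1.0, proto.nominal_speed / 300.0
    )
    if proto.protocol == "head_fixed" and proto.illumination == "light":
        strength = 0.0
    if strength == 0.0:
        return np.ones_like(tg)
    t_pre, t_rot, _ = proto.phase_times
    g = np.ones_like(tg)
    in_rot = (tg >= t_pre) & (tg < t_rot)
    g[in_rot] = 1.0 - strength * (1.0 - np.exp(-(tg[in_rot] - t_pre) / proto.disorientation_tau))
    g_end = 1.0 - strength * (1.0 - np.exp(-(t_rot - t_pre) / proto.disorientation_tau))
    in_rec = tg >= t_rot
    g[in_rec] = 1.0 - (1.0 - g_end) * np.exp(-(tg[in_rec] - t_rot) / proto.disorientation_tau)
    return g


def _postrotation_burst_times(proto: ProtocolSpec, t_rot_end, t_session_end):
    """Burst times after a dark head-fixed rotation: the first burst at
    rotation end, then each interburst interval equal to the rotation
    period inflated by exp(t / storage_time_constant), t the elapsed
    recovery time at the interval start (a velocity-storage signal
    decaying from the rotation speed)."""
    period = 360.0 / proto.nominal_speed
    tau = proto.storage_time_constant
    times = [0.0]
    while True:
        interval = period * np.exp(times[-1] / tau)
        nxt = times[-1] + interval
        if nxt > t_session_end - t_rot_end:
            break
        times.append(nxt)
    return t_rot_end + np.asarray(times)


def _vm_shape(delta_deg, kappa):
    """von Mises tuning shape, 1 at delta = 0."""
    return np.exp(kappa * (np.cos(np.radians(delta_deg)) - 1.0))


def generate_spikes(
    cell: CellSpec, tracking: TrackingSeries, proto: ProtocolSpec, seed=None
) -> SpikeTrain:
    """Simulate one cell's spike train for a tracked session.

    The rate is background + (peak - background) * vonMises(HD - PFD_eff)
    on a 1 ms grid, thinned as an inhomogeneous Poisson process.
    PFD_eff follows the cell's true PFD plus accumulated dark Brownian
    drift and, during head-fixed rotation, the accumulated
    angular-velocity underestimation (shifting the PFD in the rotation
    direction).  After a dark head-fixed rotation ends, the cell emits
    burst packets at the velocity-storage crossing times, slowing
    exponentially from the rotation period.
    """
    rng = np.random.default_rng(seed)
    t_pre, t_rot, t_end = proto.phase_times

    hd_track = _true_heading(tracking)
    uw = unwrap_deg(hd_track)
    tg = np.arange(tracking.t[0], tracking.t[-1], DT_SPIKES)
    hd = np.interp(tg, tracking.t, uw)

    # effective-PFD offset path
    offset = np.zeros(len(tg))
    if proto.illumination == "dark" and proto.drift_rate_dark > 0:
        sd_step = proto.drift_rate_dark / np.sqrt(60.0) * np.sqrt(DT_SPIKES)
        offset += np.cumsum(rng.normal(0.0, sd_step, size=len(tg)))
    if proto.protocol == "head_fixed" and proto.underestimation != 0.0:
        in_rot = (tg >= t_pre) & (tg < t_rot)
        lag = np.zeros(len(tg))
        lag[in_rot] = proto.direction_sign * proto.underestimation * DT_SPIKES
        offset += np.cumsum(lag)

    delta = hd - (cell.preferred_direction + offset)
    gain = _tuning_gain_trace(tg, proto)
    rate = cell.background_rate + gain * (
        cell.peak_rate - cell.background_rate
    ) * _vm_shape(delta, cell.tuning_concentration)

    if cell.ahv_gain != 0.0:
        ahv = np.gradient(hd, DT_SPIKES)
        rate *= 1.0 + cell.ahv_gain * np.abs(ahv) / 100.0

    bursting = (
        proto.protocol == "head_fixed"
        and proto.illumination == "dark"
        and proto.durations[1] > 0
        and proto.durations[2] > 0
        and proto.storage_time_constant > 0
    )
    if bursting:
        in_rec = tg >= t_rot
        rate[in_rec] = cell.background_rate  # tuning silent: head is stationary off-PFD
        burst_t = _postrotation_burst_times(proto, t_rot, t_end)
        halfwidth = np.degrees(
            np.arccos(1.0 + np.log(0.5) / cell.tuning_concentration)
        )  # tuning half-width at half height
        for bt in burst_t:
            speed = proto.nominal_speed * np.exp(-(bt - t_rot) / proto.storage_time_constant)
            # packet width = time for the internal sweep to cross the
            # field; amplitude above the in-field rate, as rebound
            # bursts ride on a silent background
            sigma = np.clip(halfwidth / (2.0 * speed), 0.10, 0.5)
            rate += 1.5 * cell.peak_rate * np.exp(-0.5 * ((tg - bt) / sigma) ** 2)

    counts = rng.poisson(rate * DT_SPIKES)
    idx = np.repeat(np.arange(len(tg)), counts)
    times = tg[idx] + rng.uniform(0.0, DT_SPIKES, size=len(idx))
    times.sort()
    meta = {"bursting": bursting}
    return SpikeTrain(times, float(tracking.t[0]), float(t_end), cell.cell_id, meta)


def generate_session(
    cells, proto: ProtocolSpec, seed=None
) -> SyntheticSession:
    """Generate tracking and spikes for one or more cells.

    Identical ``seed`` and specs give bit-identical output; per-cell
    spike seeds are derived from the session seed.
    """
    if isinstance(cells, CellSpec):
        cells = [cells]
    ss = np.random.SeedSequence(seed if seed is not None else proto.seed)
    track_seed, *cell_seeds = ss.spawn(1 + len(cells))
    tracking = generate_tracking(proto, seed=track_seed)
    spikes = [
        generate_spikes(c, tracking, proto, seed=s) for c, s in zip(cells, cell_seeds)
    ]
    return SyntheticSession(tracking, spikes, list(cells), proto)
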