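"""Shared synthetic sessions (generated once per test run)."""

import numpy as np
import pytest
from scipy.signal import lfilter

import hddisorient as hdd
from hddisorient.tracking import HeadDirectionSeries


@pytest.fixture(scope="session")
def baseline_session():
    """8-min light foraging baseline with one well-tuned cell."""
    proto = hdd.ProtocolSpec.baseline(duration=480.0, illumination="light")
    cell = hdd.CellSpec(
        preferred_direction=120.0, peak_rate=35.0, background_rate=1.0,
        tuning_concentration=4.0,
    )
    return hdd.generate_session(cell, proto, seed=11)


@pytest.fixture(scope="session")
def baseline_hd(baseline_session):
    return hdd.compute_hd_ahv(baseline_session.tracking)


@pytest.fixture(scope="session")
def headfixed_dark_session():
    """Head-fixed dark rotation (186 deg/s CW) with postrotational bursting."""
    proto = hdd.ProtocolSpec.head_fixed(
        speed=186.0, illumination="dark", direction="CW",
        durations=(30.0, 60.0, 120.0), underestimation=5.0,
    )
    cell = hdd.CellSpec(preferred_direction=40.0)
    return hdd.generate_session(cell, proto, seed=21)


@pytest.fixture(scope="session")
def headfixed_dark_hd(headfixed_dark_session):
    return hdd.compute_hd_ahv(headfixed_dark_session.tracking)


def make_random_walk_hd(duration_s, seed, fs=60.0, omega_sd=90.0, tau=0.35):
    """Ornstein-Uhlenbeck angular-velocity random walk as a
    HeadDirectionSeries (fast path for calibration runs)."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    dt = 1.0 / fs
    a = np.exp(-dt / tau)
    eps = rng.normal(0.0, omega_sd * np.sqrt(1 - a * a), size=n)
    eps[0] = rng.normal(0.0, omega_sd)
    omega = lfilter([1.0], [1.0, -a], eps)
    t = np.arange(n) * dt
    hd = np.mod(np.cumsum(omega) * dt, 360.0)
    return HeadDirectionSeries(t, hd, omega)
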