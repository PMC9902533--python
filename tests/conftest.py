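"""Shared fixtures: small programmatically generated traces and scans."""

from __future__ import annotations

import numpy as np
import pytest

from digisense import ExperimentGeometry, PhotonTrace


def trace_from_seconds(times_s, duration, tick=16e-12, **meta) -> PhotonTrace:
    """Build a trace from arrival times given in seconds."""
    ticks = np.round(np.asarray(times_s, dtype=float) / tick).astype(np.int64)
    return PhotonTrace(timestamps=ticks, duration=duration, tick_resolution=tick, **meta)


@pytest.fixture
def geometry() -> ExperimentGeometry:
    """Geometry of the reference device (chamber, scan step, confocal spot)."""
    return ExperimentGeometry(h=28.0, d_step=31.7, z=3.0, w=0.4, Q_sample=70.0, t=5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
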