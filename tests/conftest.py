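"""Shared fixtures: small hand-built tracks and synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wearpa import intensity, pipeline, synthetic


def make_track(
    seconds,
    lat=None,
    lon=None,
    hr=None,
    pid="P01",
    start="2022-01-10 08:00:00",
    lat0=49.88,
    lon0=-119.49,
):
    """Build a raw fix DataFrame from offsets in seconds (and optional
    per-fix lat/lon/heart-rate arrays)."""
    n = len(seconds)
    t0 = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "timestamp": [t0 + pd.Timedelta(seconds=float(s)) for s in seconds],
            "lat": np.full(n, lat0) if lat is None else np.asarray(lat, float),
            "lon": np.full(n, lon0) if lon is None else np.asarray(lon, float),
            "elevation": 350.0,
            "heart_rate": np.full(n, 80.0) if hr is None else np.asarray(hr, float),
        }
    )


def walk_track(duration_s, speed_ms, dt_s=5.0, hr=80.0, pid="P01", lat0=49.88, lon0=-119.49,
               start="2022-01-10 08:00:00"):
    """Straight northward walk at constant speed."""
    n = int(duration_s / dt_s) + 1
    secs = np.arange(n) * dt_s
    lat = lat0 + speed_ms * secs / 111_320.0
    return make_track(secs, lat=lat, lon=np.full(n, lon0), hr=np.full(n, hr), pid=pid, start=start)


@pytest.fixture
def profile_70_60():
    """Age 70, resting 60 bpm: max 150, HRR 90, cuts at 78 and 96 bpm."""
    return intensity.build_profile("P01", 70, [60.0])


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-participant, 4-day device-level cohort (fast, models skipped)."""
    frames = synthetic.simulate_cohort_frames(synthetic.SimConfig(seed=5, n_participants=4, n_days=4))
    result = pipeline.process_cohort(
        frames.gps, frames.wearable, frames.participants, frames.footprints, frames.weather,
        fit_models=False,
    )
    return frames, result


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-sized cohort (40 participants x 10 days) processed
    end to end, including the nine model fits.  Heavy: built once per
    session and stripped of fix-level frames to bound memory."""
    frames = synthetic.simulate_cohort_frames(synthetic.SimConfig(seed=7))
    result = pipeline.process_cohort(
        frames.gps, frames.wearable, frames.participants, frames.footprints, frames.weather
    )
    slim = {
        "daily": result["daily"],
        "analysis_table": result["analysis_table"],
        "model_results": result["model_results"],
        "manifest": result["manifest"],
        "trips": result["trips"],
        "stops": result["stops"],
        "truth": frames.truth,
        "participants": frames.participants,
        "n_raw_fixes": len(frames.gps),
    }
    return slim
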