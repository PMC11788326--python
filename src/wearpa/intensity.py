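"""Heart-rate-reserve (HRR) intensity classification.

Each participant gets one profile for the whole study period:

    max HR  = 220 − age
    HRR     = max HR − resting HR   (resting HR = mean of daily values)
    SB      : HR < resting + 0.20·HRR
    LPA     : resting + 0.20·HRR ≤ HR < resting + 0.40·HRR
    MVPA    : HR ≥ resting + 0.40·HRR

The LPA/MVPA boundary is inclusive on the MVPA side; the three bands
partition the heart-rate line.  Heart rates are classified as-is, without
rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .trajectory import split_intervals_by_day

__all__ = [
    "SB_FRACTION",
    "MVPA_FRACTION",
    "HrrProfile",
    "mean_resting_hr",
    "build_profile",
    "classify_intensity",
    "summarize_daily_intensity",
    "INTENSITY_CLASSES",
]

SB_FRACTION = 0.20
MVPA_FRACTION = 0.40
INTENSITY_CLASSES = ("SB", "LPA", "MVPA")


@dataclass(frozen=True)
class HrrProfile:
    """Per-participant heart-rate thresholds derived from age and resting HR."""

    participant_id: str
    resting_hr: float
    max_hr: float
    hrr: float
    cut_sb: float
    cut_mvpa: float

    def __post_init__(self):
        if not self.hrr > 0:
            raise ValueError(
                f"{self.participant_id}: heart-rate reserve must be positive "
                f"(max {self.max_hr}, resting {self.resting_hr})"
            )


def mean_resting_hr(daily_values: Iterable[float]) -> float:
    """Arithmetic mean of the daily resting heart rates (bpm)."""
    vals = np.asarray([v for v in daily_values if not np.isnan(v)], float)
    if vals.size == 0:
        raise ValueError("no resting heart-rate values available")
    return float(vals.mean())


def build_profile(participant_id: str, age: float, daily_resting_hr: Iterable[float]) -> HrrProfile:
    """Build the study-period HRR profile for one participant."""
    resting = mean_resting_hr(daily_resting_hr)
    max_hr = 220.0 - float(age)
    hrr = max_hr - resting
    return HrrProfile(
        participant_id=participant_id,
        resting_hr=resting,
        max_hr=max_hr,
        hrr=hrr,
        cut_sb=resting + SB_FRACTION * hrr,
        cut_mvpa=resting + MVPA_FRACTION * hrr,
    )


def classify_intensity(hr, profile: HrrProfile):
    """Classify heart rate(s) into SB / LPA / MVPA for one profile.

    Scalar in, scalar out; array in, object array of labels out.
    """
    arr = np.asarray(hr, float)
    labels = np.where(arr < profile.cut_sb, "SB", np.where(arr < profile.cut_mvpa, "LPA", "MVPA"))
    if np.isscalar(hr) or arr.ndim == 0:
        return str(labels)
    return labels


def summarize_daily_intensity(track: pd.DataFrame, profile: HrrProfile) -> pd.DataFrame:
    """Minutes of SB/LPA/MVPA per date for one participant's cleaned track.

    Each worn forward interval is assigned to the intensity class of its
    fix's heart rate; intervals are split at midnight.  For every day,
    sb_min + lpa_min + mvpa_min equals wear_min.
    """
    track = track.copy()
    track["intensity"] = classify_intensity(track["heart_rate"].to_numpy(float), profile)
    iv = split_intervals_by_day(track, carry=["intensity"])
    if iv.empty:
        return pd.DataFrame(
            columns=["participant_id", "date", "sb_min", "lpa_min", "mvpa_min", "wear_min"]
        )
    mins = (
        iv.pivot_table(
            index=["participant_id", "date"],
            columns="intensity",
            values="seconds",
            aggfunc="sum",
            fill_value=0.0,
        )
        / 60.0
    )
    for cls in INTENSITY_CLASSES:
        if cls not in mins.columns:
            mins[cls] = 0.0
    out = mins.rename(columns={"SB": "sb_min", "LPA": "lpa_min", "MVPA": "mvpa_min"})
    out = out[["sb_min", "lpa_min", "mvpa_min"]].reset_index()
    out["wear_min"] = out[["sb_min", "lpa_min", "mvpa_min"]].sum(axis=1)
    return out
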