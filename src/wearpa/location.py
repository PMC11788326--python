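"""Indoor/outdoor labelling of fixes against building footprints.

A fix is provisionally outdoor iff it falls strictly outside every
footprint polygon (points on a boundary count as indoor).  To keep GPS
positional error from inflating outdoor time, a provisional-outdoor run
shorter than five consecutive fixes is relabelled indoor.  Runs are broken
by participant changes and by non-wear gaps — a run of "consecutive" fixes
cannot span a period when the device recorded nothing for an hour.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ingest import FootprintSet
from .intensity import HrrProfile, INTENSITY_CLASSES, classify_intensity
from .trajectory import split_intervals_by_day

__all__ = ["MIN_OUTDOOR_RUN", "label_indoor_outdoor", "summarize_by_location", "LOCATION_COLUMNS"]

MIN_OUTDOOR_RUN = 5

LOCATION_COLUMNS = [
    f"{cls.lower()}_{loc}_min" for cls in INTENSITY_CLASSES for loc in ("in", "out")
]


def label_indoor_outdoor(
    track: pd.DataFrame, footprints: FootprintSet, min_run: int = MIN_OUTDOOR_RUN
) -> np.ndarray:
    """Label every fix ``"indoor"`` or ``"outdoor"``.

    The run rule only ever converts outdoor fixes to indoor, never the
    reverse.  Returns an object array aligned with ``track`` rows.
    """
    n = len(track)
    if n == 0:
        return np.empty(0, object)
    outdoor = ~footprints.contains_xy(track["lon"].to_numpy(float), track["lat"].to_numpy(float))

    # Break consecutive runs at participant changes and non-wear gaps.
    pid = track["participant_id"].to_numpy()
    broken_after = np.zeros(n, bool)
    if n > 1:
        broken_after[:-1] = pid[:-1] != pid[1:]
    if "wear" in track.columns:
        broken_after |= ~track["wear"].to_numpy(bool)

    run_id = np.zeros(n, np.int64)
    if n > 1:
        new_run = np.empty(n, bool)
        new_run[0] = True
        new_run[1:] = (outdoor[1:] != outdoor[:-1]) | broken_after[:-1]
        run_id = np.cumsum(new_run) - 1
    lengths = np.bincount(run_id)
    short = lengths[run_id] < min_run
    outdoor = outdoor & ~short
    return np.where(outdoor, "outdoor", "indoor").astype(object)


def summarize_by_location(
    track: pd.DataFrame, profile: HrrProfile, labels: np.ndarray
) -> pd.DataFrame:
    """Minutes of SB/LPA/MVPA × indoor/outdoor per date.

    Indoor + outdoor minutes reproduce the per-class daily totals of
    :func:`wearpa.intensity.summarize_daily_intensity` exactly: the same
    worn, midnight-split intervals are summed, partitioned one level
    further by the fix's location label.
    """
    track = track.copy()
    track["intensity"] = classify_intensity(track["heart_rate"].to_numpy(float), profile)
    track["location"] = labels
    iv = split_intervals_by_day(track, carry=["intensity", "location"])
    cols = ["participant_id", "date", *LOCATION_COLUMNS]
    if iv.empty:
        return pd.DataFrame(columns=cols)
    mins = (
        iv.pivot_table(
            index=["participant_id", "date"],
            columns=["intensity", "location"],
            values="seconds",
            aggfunc="sum",
            fill_value=0.0,
        )
        / 60.0
    )
    out = pd.DataFrame(index=mins.index)
    for cls in INTENSITY_CLASSES:
        for loc, tag in (("indoor", "in"), ("outdoor", "out")):
            col = (cls, loc)
            out[f"{cls.lower()}_{tag}_min"] = mins[col] if col in mins.columns else 0.0
    return out.reset_index()[cols]
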