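"""Stops, trips, transport mode and outdoor walking time.

Inclusion rules run first: participant-days with under nine hours of wear
time are dropped, then participants left with fewer than four days.

Within each participant-day (runs also break at non-wear gaps) a greedy
left-to-right scan clusters consecutive slow fixes into "stops" — places
of interest where speeds stay below 0.5 m/s for at least two minutes
within 150 m of the running centroid.  Maximal runs of the remaining
in-transit fixes are candidate trips; a candidate is a trip iff it lasts
at least 3 minutes, covers at least 100 m and has a mean speed of at
least 1 km/h.  Transport mode comes from the 90th-percentile per-fix
speed: [1, 10) km/h walking, [10, 25) km/h biking, ≥25 km/h vehicular.
Outdoor walking minutes are the worn intervals of walking-trip fixes
labelled outdoor, summed per day.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .trajectory import (
    EARTH_RADIUS_M as trajectory_EARTH_RADIUS,
    daily_wear_minutes,
    split_intervals_by_day,
)

__all__ = [
    "STOP_SPEED_MS",
    "STOP_MIN_DURATION_S",
    "STOP_RADIUS_M",
    "TRIP_MIN_DURATION_MIN",
    "TRIP_MIN_LENGTH_M",
    "TRIP_MIN_MEAN_KMH",
    "MODE_BANDS_KMH",
    "MIN_DAY_HOURS",
    "MIN_VALID_DAYS",
    "InclusionResult",
    "apply_inclusion",
    "detect_stops",
    "segment_trips",
    "classify_mode",
    "outdoor_walking_minutes",
]

STOP_SPEED_MS = 0.5
STOP_MIN_DURATION_S = 120.0
STOP_RADIUS_M = 150.0
TRIP_MIN_DURATION_MIN = 3.0
TRIP_MIN_LENGTH_M = 100.0
TRIP_MIN_MEAN_KMH = 1.0
#: Half-open 90th-percentile speed bands, km/h.
MODE_BANDS_KMH = {"walking": (1.0, 10.0), "biking": (10.0, 25.0), "vehicular": (25.0, np.inf)}
MIN_DAY_HOURS = 9.0
MIN_VALID_DAYS = 4


class InclusionResult(NamedTuple):
    track: pd.DataFrame
    kept_days: pd.DataFrame  # participant_id, date, wear_min for surviving days
    dropped_days: pd.DataFrame  # days excluded for wear < MIN_DAY_HOURS
    dropped_participants: list  # participants excluded for < MIN_VALID_DAYS days
    all_days: pd.DataFrame  # every participant-day with wear minutes, pre-exclusion


def apply_inclusion(
    track: pd.DataFrame,
    min_hours: float = MIN_DAY_HOURS,
    min_days: int = MIN_VALID_DAYS,
) -> InclusionResult:
    """Drop short days, then participants with too few surviving days.

    Day order matters: the day rule is applied first, the participant rule
    to the days that survive it.
    """
    wear = daily_wear_minutes(track)
    short = wear["wear_min"] < min_hours * 60.0
    kept = wear.loc[~short]
    days_per = kept.groupby("participant_id").size()
    bad_pids = sorted(days_per.index[days_per < min_days])
    kept = kept.loc[~kept["participant_id"].isin(bad_pids)]

    fix_key = pd.DataFrame(
        {
            "participant_id": track["participant_id"].to_numpy(),
            "date": pd.to_datetime(track["timestamp"]).dt.normalize().to_numpy(),
        }
    )
    merged = fix_key.merge(
        kept[["participant_id", "date"]],
        on=["participant_id", "date"],
        how="left",
        indicator=True,
    )
    keep_mask = (merged["_merge"] == "both").to_numpy()
    out = track.loc[keep_mask].reset_index(drop=True)
    return InclusionResult(
        track=out,
        kept_days=kept.reset_index(drop=True),
        dropped_days=wear.loc[short].reset_index(drop=True),
        dropped_participants=bad_pids,
        all_days=wear,
    )


def _segment_ids(track: pd.DataFrame) -> np.ndarray:
    """Scan-unit id per fix: breaks at participant change, date change, non-wear gap."""
    n = len(track)
    if n == 0:
        return np.empty(0, np.int64)
    pid = pd.factorize(track["participant_id"])[0]
    date = pd.to_datetime(track["timestamp"]).dt.normalize().to_numpy("datetime64[D]")
    new = np.empty(n, bool)
    new[0] = True
    if n > 1:
        new[1:] = (pid[1:] != pid[:-1]) | (date[1:] != date[:-1])
        if "wear" in track.columns:
            new[1:] |= ~track["wear"].to_numpy(bool)[:-1]
    return np.cumsum(new) - 1


def detect_stops(track: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster slow fixes into stops.

    Returns ``(stops, in_stop)`` where ``stops`` has one row per stop
    (participant, date, start, end, centroid, member first/last row
    positions) and ``in_stop`` is a boolean mask over ``track`` rows.
    Stops and in-transit fixes partition each scan unit.
    """
    n = len(track)
    in_stop = np.zeros(n, bool)
    records: list[dict] = []
    if n == 0:
        return _stops_frame(records), in_stop

    seg = _segment_ids(track)
    ts = pd.to_datetime(track["timestamp"]).to_numpy("datetime64[ns]")
    lat = track["lat"].to_numpy(float)
    lon = track["lon"].to_numpy(float)
    speed = track["fwd_speed_ms"].to_numpy(float)
    pid = track["participant_id"].to_numpy()
    slow = speed < STOP_SPEED_MS  # NaN speed (last fix) is not slow
    # local planar meters for the centroid-radius test (equirectangular;
    # sub-centimeter error against the sphere at the 150 m scale)
    lat0 = np.radians(np.nanmean(lat))
    ym = np.radians(lat) * trajectory_EARTH_RADIUS
    xm = np.radians(lon) * trajectory_EARTH_RADIUS * np.cos(lat0)

    fwd_dt = track["fwd_dt_s"].to_numpy(float)
    worn = track["wear"].to_numpy(bool) if "wear" in track.columns else ~np.isnan(fwd_dt)

    def _finalize(members: list[int]):
        # the slow time is the sum of the members' worn forward intervals
        # (a member's interval is exactly the stretch its speed describes)
        m = np.asarray(members)
        dur = float(fwd_dt[m[worn[m]]].sum())
        if dur >= STOP_MIN_DURATION_S:
            in_stop[members] = True
            end = ts[members[-1]] + np.timedelta64(int(round(fwd_dt[members[-1]])), "s") if worn[
                members[-1]
            ] else ts[members[-1]]
            records.append(
                {
                    "participant_id": pid[members[0]],
                    "date": pd.Timestamp(ts[members[0]]).normalize(),
                    "start": pd.Timestamp(ts[members[0]]),
                    "end": pd.Timestamp(end),
                    "centroid_lat": float(np.mean(lat[members])),
                    "centroid_lon": float(np.mean(lon[members])),
                    "first_idx": members[0],
                    "last_idx": members[-1],
                    "n_fixes": len(members),
                }
            )

    members: list[int] = []
    sx = sy = 0.0  # running sums of member x/y; centroid = sums / len(members)
    r2 = STOP_RADIUS_M**2
    for i in range(n):
        if members and seg[i] != seg[members[-1]]:
            _finalize(members)
            members = []
        if slow[i]:
            if members:
                k = len(members)
                dx = xm[i] - sx / k
                dy = ym[i] - sy / k
                if dx * dx + dy * dy <= r2:
                    members.append(i)
                    sx += xm[i]
                    sy += ym[i]
                    continue
                _finalize(members)
            members = [i]
            sx, sy = xm[i], ym[i]
        elif members:
            _finalize(members)
            members = []
    if members:
        _finalize(members)
    return _stops_frame(records), in_stop


def _stops_frame(records: list[dict]) -> pd.DataFrame:
    cols = [
        "participant_id",
        "date",
        "start",
        "end",
        "centroid_lat",
        "centroid_lon",
        "first_idx",
        "last_idx",
        "n_fixes",
    ]
    return pd.DataFrame(records, columns=cols)


def classify_mode(p90_kmh: float) -> str:
    """Transport mode from a trip's 90th-percentile speed (km/h)."""
    if np.isnan(p90_kmh) or p90_kmh < MODE_BANDS_KMH["walking"][0]:
        return "none"
    for mode, (lo, hi) in MODE_BANDS_KMH.items():
        if lo <= p90_kmh < hi:
            return mode
    return "none"  # pragma: no cover


def segment_trips(track: pd.DataFrame, in_stop: np.ndarray) -> pd.DataFrame:
    """Screen maximal in-transit runs into trips and classify their mode.

    Candidates failing the ≥3 min / ≥100 m / ≥1 km/h screen keep
    ``mode="none"``.  Per-fix speeds feeding the 90th percentile are the
    forward speeds between consecutive fixes of the segment (linear
    interpolation between order statistics).
    """
    n = len(track)
    cols = [
        "participant_id",
        "date",
        "start",
        "end",
        "duration_min",
        "length_m",
        "mean_kmh",
        "p90_kmh",
        "mode",
        "first_idx",
        "last_idx",
    ]
    if n == 0:
        return pd.DataFrame(columns=cols)
    seg = _segment_ids(track)
    ts = pd.to_datetime(track["timestamp"]).to_numpy("datetime64[ns]")
    dist = track["fwd_dist_m"].to_numpy(float)
    speed = track["fwd_speed_ms"].to_numpy(float)
    pid = track["participant_id"].to_numpy()

    transit = ~np.asarray(in_stop, bool)
    new_run = np.empty(n, bool)
    new_run[0] = True
    new_run[1:] = (transit[1:] != transit[:-1]) | (seg[1:] != seg[:-1])
    run_id = np.cumsum(new_run) - 1

    records = []
    for rid in np.unique(run_id[transit]):
        idx = np.flatnonzero((run_id == rid) & transit)
        first, last = idx[0], idx[-1]
        duration_min = float((ts[last] - ts[first]) / np.timedelta64(1, "m"))
        inner = idx[:-1]  # forward legs internal to the segment
        length_m = float(np.nansum(dist[inner])) if inner.size else 0.0
        mean_kmh = (length_m / (duration_min * 60.0)) * 3.6 if duration_min > 0 else 0.0
        leg_speeds = speed[inner]
        leg_speeds = leg_speeds[~np.isnan(leg_speeds)]
        p90_kmh = float(np.percentile(leg_speeds * 3.6, 90)) if leg_speeds.size else np.nan
        is_trip = (
            duration_min >= TRIP_MIN_DURATION_MIN
            and length_m >= TRIP_MIN_LENGTH_M
            and mean_kmh >= TRIP_MIN_MEAN_KMH
        )
        records.append(
            {
                "participant_id": pid[first],
                "date": pd.Timestamp(ts[first]).normalize(),
                "start": pd.Timestamp(ts[first]),
                "end": pd.Timestamp(ts[last]),
                "duration_min": duration_min,
                "length_m": length_m,
                "mean_kmh": mean_kmh,
                "p90_kmh": p90_kmh,
                "mode": classify_mode(p90_kmh) if is_trip else "none",
                "first_idx": int(first),
                "last_idx": int(last),
            }
        )
    return pd.DataFrame(records, columns=cols)


def outdoor_walking_minutes(
    track: pd.DataFrame, trips: pd.DataFrame, labels: np.ndarray
) -> pd.DataFrame:
    """Daily minutes spent on outdoor fixes of walking trips.

    Sums the worn forward intervals (midnight-split) of walking-trip
    member fixes labelled outdoor; the final fix of each trip contributes
    no interval, matching the trip's duration definition.
    """
    mask = np.zeros(len(track), bool)
    for t in trips.itertuples(index=False):
        if t.mode == "walking":
            mask[t.first_idx : t.last_idx] = True  # last fix excluded
    sub = track.loc[mask & (np.asarray(labels, object) == "outdoor")]
    iv = split_intervals_by_day(sub)
    if iv.empty:
        return pd.DataFrame(columns=["participant_id", "date", "walk_out_min"])
    g = iv.groupby(["participant_id", "date"], sort=True)["seconds"].sum() / 60.0
    return g.rename("walk_out_min").reset_index()
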