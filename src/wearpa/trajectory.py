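"""Fix-level cleaning of GPS traces.

The cleaning chain runs in a fixed order:

    drop_incomplete -> compute_kinematics -> remove_outliers
        -> dedupe_timestamps -> flag_nonwear

Forward kinematics (distance, interval, speed to the *next* fix) are
attached to the earlier fix of each pair; the last fix of a participant's
trace carries no kinematics.  A fix is an outlier iff its forward speed
exceeds 50 m/s or its forward distance exceeds 30 m (strict inequalities);
kinematics are recomputed once over the survivors, not iterated.  Gaps of
at least 60 minutes between consecutive fixes are non-wear time.

All functions accept a DataFrame of fixes for one or many participants
(grouped internally by ``participant_id``) and never reorder rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_M",
    "SPEED_LIMIT_MS",
    "DISTANCE_LIMIT_M",
    "NONWEAR_GAP_MIN",
    "haversine_m",
    "drop_incomplete",
    "compute_kinematics",
    "remove_outliers",
    "dedupe_timestamps",
    "flag_nonwear",
    "clean_track",
    "split_intervals_by_day",
    "daily_wear_minutes",
]

EARTH_RADIUS_M = 6_371_000.0
SPEED_LIMIT_MS = 50.0
DISTANCE_LIMIT_M = 30.0
NONWEAR_GAP_MIN = 60.0


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in meters on a sphere of radius 6,371 km."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def drop_incomplete(fixes: pd.DataFrame) -> pd.DataFrame:
    """Remove fixes lacking a coordinate or a heart-rate measure."""
    keep = fixes["lat"].notna() & fixes["lon"].notna() & fixes["heart_rate"].notna()
    return fixes.loc[keep].reset_index(drop=True)


def _participant_breaks(fixes: pd.DataFrame) -> np.ndarray:
    """True where a row is the last fix of its participant's block."""
    pid = pd.factorize(fixes["participant_id"])[0]
    last = np.ones(len(fixes), bool)
    if len(fixes) > 1:
        last[:-1] = pid[:-1] != pid[1:]
    return last


def compute_kinematics(fixes: pd.DataFrame) -> pd.DataFrame:
    """Attach forward distance (m), interval (s) and speed (m/s) per fix.

    The last fix of each participant gets NaN kinematics.  A zero-length
    interval (duplicate timestamp, removed downstream) yields NaN speed —
    speed is undefined, not infinite, there.

    Raises
    ------
    ValueError
        If timestamps decrease within a participant.
    """
    out = fixes.reset_index(drop=True).copy()
    n = len(out)
    dist = np.full(n, np.nan)
    dt = np.full(n, np.nan)
    if n:
        ts = pd.to_datetime(out["timestamp"]).to_numpy("datetime64[ns]")
        last = _participant_breaks(out)
        fwd = ~last
        if fwd.any():
            i = np.flatnonzero(fwd)
            dsec = (ts[i + 1] - ts[i]) / np.timedelta64(1, "s")
            if (dsec < 0).any():
                bad = out.loc[i[dsec < 0][0], "participant_id"]
                raise ValueError(f"timestamps decrease within participant {bad!r}")
            lat = out["lat"].to_numpy(float)
            lon = out["lon"].to_numpy(float)
            dist[i] = haversine_m(lat[i], lon[i], lat[i + 1], lon[i + 1])
            dt[i] = dsec
    with np.errstate(invalid="ignore", divide="ignore"):
        speed = np.where(dt > 0, dist / dt, np.nan)
    out["fwd_dist_m"] = dist
    out["fwd_dt_s"] = dt
    out["fwd_speed_ms"] = speed
    return out


def remove_outliers(track: pd.DataFrame) -> pd.DataFrame:
    """Drop fixes whose forward speed > 50 m/s or forward distance > 30 m.

    Strict inequalities; the predicate attaches to the earlier fix of the
    pair.  Kinematics are recomputed exactly once over the survivors.
    """
    bad = (track["fwd_speed_ms"] > SPEED_LIMIT_MS) | (track["fwd_dist_m"] > DISTANCE_LIMIT_M)
    if not bad.any():
        return track.reset_index(drop=True)
    return compute_kinematics(track.loc[~bad].drop(columns=["fwd_dist_m", "fwd_dt_s", "fwd_speed_ms"]))


def dedupe_timestamps(track: pd.DataFrame) -> pd.DataFrame:
    """Keep only the earliest-in-file fix of each duplicate-timestamp group."""
    keep = ~track.duplicated(["participant_id", "timestamp"])
    if keep.all():
        return track
    return compute_kinematics(
        track.loc[keep].drop(columns=["fwd_dist_m", "fwd_dt_s", "fwd_speed_ms"], errors="ignore")
    )


def flag_nonwear(track: pd.DataFrame, gap_minutes: float = NONWEAR_GAP_MIN) -> pd.DataFrame:
    """Mark each fix's forward interval as wear or non-wear.

    An interval of at least ``gap_minutes`` is non-wear.  The last fix of a
    participant has no forward interval and is flagged non-wear (it
    contributes no time to any summary).
    """
    return track.assign(wear=(track["fwd_dt_s"] < gap_minutes * 60.0).to_numpy())


def clean_track(fixes: pd.DataFrame, gap_minutes: float = NONWEAR_GAP_MIN) -> pd.DataFrame:
    """Run the full cleaning chain on raw fixes."""
    return flag_nonwear(
        dedupe_timestamps(remove_outliers(compute_kinematics(drop_incomplete(fixes)))),
        gap_minutes=gap_minutes,
    )


def split_intervals_by_day(track: pd.DataFrame, carry: list[str] | None = None) -> pd.DataFrame:
    """One row per worn forward interval, split at local midnight.

    Each fix contributes its forward interval to the calendar date of its
    own timestamp; an interval spanning midnight is split so each day gets
    its share.  Columns: ``participant_id, date, seconds`` plus any
    ``carry`` columns copied from the source fix.

    Only worn intervals (see :func:`flag_nonwear`) contribute.
    """
    carry = carry or []
    worn = track.loc[track["wear"]]
    if worn.empty:
        return pd.DataFrame(columns=["participant_id", "date", "seconds", *carry])
    ts = pd.to_datetime(worn["timestamp"])
    start_day = ts.dt.normalize()
    end = ts + pd.to_timedelta(worn["fwd_dt_s"], unit="s")
    crosses = end.dt.normalize() > start_day

    base = pd.DataFrame(
        {
            "participant_id": worn["participant_id"].to_numpy(),
            "date": start_day.to_numpy(),  # normalized datetime64 (midnight)
            "seconds": worn["fwd_dt_s"].to_numpy(float),
        }
    )
    for c in carry:
        base[c] = worn[c].to_numpy()
    if not crosses.any():
        return base

    rows = [base.loc[~crosses.to_numpy()]]
    cross = worn.loc[crosses]
    cts = pd.to_datetime(cross["timestamp"])
    cend = cts + pd.to_timedelta(cross["fwd_dt_s"], unit="s")
    for (_, fix), t0, t1 in zip(cross.iterrows(), cts, cend):
        # walk midnight boundaries; worn intervals are short so this loop
        # runs once per crossing in practice
        cur = t0
        while cur < t1:
            nxt = min((cur.normalize() + pd.Timedelta(days=1)), t1)
            rec = {
                "participant_id": fix["participant_id"],
                "date": cur.normalize(),
                "seconds": (nxt - cur).total_seconds(),
            }
            for c in carry:
                rec[c] = fix[c]
            rows.append(pd.DataFrame([rec]))
            cur = nxt
    return pd.concat(rows, ignore_index=True)


def daily_wear_minutes(track: pd.DataFrame) -> pd.DataFrame:
    """Wear time in minutes per participant-day (midnight-split intervals)."""
    iv = split_intervals_by_day(track)
    if iv.empty:
        return pd.DataFrame(columns=["participant_id", "date", "wear_min"])
    g = iv.groupby(["participant_id", "date"], sort=True)["seconds"].sum() / 60.0
    return g.rename("wear_min").reset_index()
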