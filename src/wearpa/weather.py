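"""Day-level weather exposures and the participant-day analysis table.

Weather exposures:

* freeze-thaw day: minimum temperature at or below 0 °C **and** maximum
  above 0 °C on the same day;
* tropical night: minimum temperature never below 20 °C;
* daylight hours: time between sunrise and sunset from the standard NOAA
  solar-position approximation (zenith 90.833°), used only when the
  weather file lacks a ``daylight`` column.

Each participant is matched once to the weather station nearest their
residence (great-circle distance, ties broken by lowest station id), and
participant-day outcome rows are joined to that station's records by
date.  The merge preserves the outcome rows exactly: a day with no
usable weather is flagged ``incomplete``, never dropped, and a missing
mean temperature is flagged rather than imputed from (tmin+tmax)/2.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .trajectory import haversine_m

__all__ = [
    "flag_freeze_thaw",
    "flag_tropical_night",
    "daylight_hours",
    "assign_station",
    "nearest_station_merge",
    "TROPICAL_NIGHT_TMIN",
]

TROPICAL_NIGHT_TMIN = 20.0


def flag_freeze_thaw(tmin, tmax):
    """1 iff tmin ≤ 0 °C and tmax > 0 °C (element-wise)."""
    tmin = np.asarray(tmin, float)
    tmax = np.asarray(tmax, float)
    out = ((tmin <= 0.0) & (tmax > 0.0)).astype(int)
    return out if out.ndim else int(out)


def flag_tropical_night(tmin):
    """1 iff the daily minimum never fell below 20 °C (element-wise)."""
    tmin = np.asarray(tmin, float)
    out = (tmin >= TROPICAL_NIGHT_TMIN).astype(int)
    return out if out.ndim else int(out)


def daylight_hours(lat: float, lon: float, date: dt.date) -> float:
    """Hours between sunrise and sunset (NOAA approximation).

    Uses the NOAA low-accuracy solar position series with the standard
    refraction-corrected zenith of 90.833°.  Longitude does not affect the
    day length itself and is accepted for interface symmetry.  Polar day
    and night clamp to 24 and 0 hours.
    """
    date = pd.Timestamp(date)
    doy = date.dayofyear
    gamma = 2.0 * np.pi / 365.0 * (doy - 1 + (12 - 12) / 24)
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    phi = np.radians(lat)
    zenith = np.radians(90.833)
    cos_ha = (np.cos(zenith) - np.sin(phi) * np.sin(decl)) / (np.cos(phi) * np.cos(decl))
    if cos_ha <= -1.0:
        return 24.0  # polar day
    if cos_ha >= 1.0:
        return 0.0  # polar night
    ha = np.degrees(np.arccos(cos_ha))
    return float(2.0 * ha / 15.0)


def assign_station(participants: pd.DataFrame, stations: pd.DataFrame) -> pd.Series:
    """Nearest station id per participant (haversine; ties -> lowest id).

    ``stations`` needs columns ``station_id, lat, lon``.
    """
    st = stations.drop_duplicates("station_id").sort_values("station_id")
    chosen = {}
    for p in participants.itertuples(index=False):
        d = haversine_m(p.res_lat, p.res_lon, st["lat"].to_numpy(), st["lon"].to_numpy())
        # stable argmin over the id-sorted frame implements the tie-break
        chosen[p.participant_id] = st["station_id"].to_numpy()[int(np.argmin(d))]
    return pd.Series(chosen, name="station_id")


def nearest_station_merge(
    participants: pd.DataFrame,
    weather: pd.DataFrame,
    daily_summaries: pd.DataFrame,
    daily_wearable: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the participant-day analysis table.

    Parameters
    ----------
    participants : roster with residence coordinates (see ingest).
    weather : station-day records; station coordinates are taken from the
        first row of each station.
    daily_summaries : one row per participant-day of outcomes (intensity ×
        location minutes, outdoor walking minutes, wear minutes).
    daily_wearable : optional steps / resting-heart-rate records merged by
        participant and date.

    Returns the outcome rows with weather, derived flags, demographics,
    a weekend flag, a 1-based ``study_day`` index and an ``incomplete``
    flag for rows lacking station weather.
    """
    stations = weather.drop_duplicates("station_id")[["station_id", "lat", "lon"]]
    stn = assign_station(participants, stations)

    out = daily_summaries.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out["station_id"] = out["participant_id"].map(stn)

    wcols = ["station_id", "date", "tmin", "tmax", "tmean", "precip", "snow"]
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"]).dt.date
    if "daylight" in w.columns:
        wcols.append("daylight")
    n_before = len(out)
    out = out.merge(w[wcols], on=["station_id", "date"], how="left", validate="m:1")
    assert len(out) == n_before  # merge must neither drop nor duplicate rows

    if "daylight" not in out.columns:
        st_pos = stations.set_index("station_id")
        out["daylight"] = [
            daylight_hours(st_pos.loc[s, "lat"], st_pos.loc[s, "lon"], d) if pd.notna(s) else np.nan
            for s, d in zip(out["station_id"], out["date"])
        ]
    out["freeze_thaw"] = flag_freeze_thaw(out["tmin"], out["tmax"])
    out["tropical_night"] = flag_tropical_night(out["tmin"])
    out["incomplete"] = out[["tmin", "tmax", "tmean", "precip", "snow", "daylight"]].isna().any(axis=1)

    if daily_wearable is not None:
        dw = daily_wearable.copy()
        dw["date"] = pd.to_datetime(dw["date"]).dt.date
        out = out.drop(
            columns=[c for c in ("steps", "resting_heart_rate") if c in out.columns]
        )
        out = out.merge(
            dw[["participant_id", "date", "steps", "resting_heart_rate"]],
            on=["participant_id", "date"],
            how="left",
            validate="1:1",
        )

    demo = participants.set_index("participant_id")
    out["age"] = out["participant_id"].map(demo["age"]).astype(float)
    out["sex_female"] = (out["participant_id"].map(demo["sex"]) == "female").astype(int)
    out["health"] = out["participant_id"].map(demo["health"]).astype(float)

    dow = pd.to_datetime(out["date"]).dt.dayofweek
    out["weekend"] = (dow >= 5).astype(int)
    first = out.groupby("participant_id")["date"].transform("min")
    out["study_day"] = (
        pd.to_datetime(out["date"]) - pd.to_datetime(first)
    ).dt.days.astype(int) + 1
    return out
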