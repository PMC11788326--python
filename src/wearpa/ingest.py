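"""Readers and writers for the external file formats of the study.

All coordinates are WGS84 decimal degrees.  Timestamps are parsed as local
civil time and kept zone-naive throughout; any UTC-offset designator in a
TCX/GPX file is dropped, not applied.  A "day" downstream is the local
calendar date of a timestamp.

GPS tracks are returned as pandas DataFrames with one row per fix and
columns ``participant_id, timestamp, lat, lon, elevation, heart_rate``
(the CSV dialect uses exactly these column names).  Readers preserve the
file's record order and never sort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree
from shapely.geometry import mapping, shape

__all__ = [
    "ParseError",
    "ValidationError",
    "FootprintSet",
    "GPS_COLUMNS",
    "read_gps_track",
    "read_daily_wearable",
    "read_weather",
    "read_participants",
    "read_footprints",
    "write_tcx",
    "write_gpx",
    "write_gps_csv",
    "write_footprints_geojson",
    "HR_PLAUSIBLE",
]

GPS_COLUMNS = ["participant_id", "timestamp", "lat", "lon", "elevation", "heart_rate"]

#: Plausibility screen for heart-rate values (bpm, exclusive bounds).
#: Out-of-range readings are treated as absent, not as errors.
HR_PLAUSIBLE = (20.0, 250.0)

_TCX_NS = "http://www.garmin.com/xmlschemas/TrainingCenterDatabase/v2"
_GPX_NS = "http://www.topografix.com/GPX/1/1"
_GPX_TPX_NS = "http://www.garmin.com/xmlschemas/TrackPointExtension/v1"


class ParseError(ValueError):
    """A file could not be parsed as its declared dialect."""


class ValidationError(ValueError):
    """A file parsed, but its content violates a domain invariant."""


# ---------------------------------------------------------------------------
# GPS tracks


def _parse_naive_timestamp(text: str) -> pd.Timestamp:
    # Local civil time: strip any trailing zone designator instead of
    # converting, so the clock time written by the device is what we keep.
    ts = pd.Timestamp(text)
    if ts.tzinfo is not None:
        ts = ts.tz_localize(None)
    return ts


def _screen_hr(hr: float) -> float:
    lo, hi = HR_PLAUSIBLE
    if not (lo < hr < hi):
        return math.nan
    return hr


def read_gps_track(path, dialect: str | None = None, participant_id: str | None = None) -> pd.DataFrame:
    """Read one participant's GPS fixes from a TCX, GPX or CSV file.

    Parameters
    ----------
    path : path-like
    dialect : {"tcx", "gpx", "csv"}, optional
        Inferred from the file suffix when omitted.
    participant_id : str, optional
        Identifier stamped on every fix; defaults to the file stem.

    Returns
    -------
    DataFrame with :data:`GPS_COLUMNS`, rows in file order.  Missing
    latitude/longitude, elevation or heart rate are NaN.
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if participant_id is None:
        participant_id = path.stem
    if dialect == "tcx":
        rows = _read_tcx(path)
    elif dialect == "gpx":
        rows = _read_gpx(path)
    elif dialect == "csv":
        return _read_gps_csv(path, participant_id)
    else:
        raise ParseError(f"unknown GPS dialect {dialect!r} (expected tcx, gpx or csv)")
    df = pd.DataFrame(rows, columns=GPS_COLUMNS[1:])
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype="float64") for c in GPS_COLUMNS[1:]})
        df["timestamp"] = pd.Series(dtype="datetime64[ns]")
        df = df[GPS_COLUMNS[1:]]
    df.insert(0, "participant_id", participant_id)
    return df


def _xml_root(path: Path):
    try:
        return etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"{path}: malformed XML: {exc}") from exc


def _read_tcx(path: Path) -> list[tuple]:
    root = _xml_root(path)
    ns = {"t": _TCX_NS}
    rows = []
    for tp in root.iterfind(".//t:Trackpoint", ns):
        time_el = tp.find("t:Time", ns)
        if time_el is None or not time_el.text:
            raise ParseError(f"{path}: Trackpoint at line {tp.sourceline} lacks <Time>")
        lat_el = tp.find("t:Position/t:LatitudeDegrees", ns)
        lon_el = tp.find("t:Position/t:LongitudeDegrees", ns)
        ele_el = tp.find("t:AltitudeMeters", ns)
        hr_el = tp.find("t:HeartRateBpm/t:Value", ns)
        rows.append(
            (
                _parse_naive_timestamp(time_el.text),
                float(lat_el.text) if lat_el is not None else math.nan,
                float(lon_el.text) if lon_el is not None else math.nan,
                float(ele_el.text) if ele_el is not None else math.nan,
                _screen_hr(float(hr_el.text)) if hr_el is not None else math.nan,
            )
        )
    return rows


def _read_gpx(path: Path) -> list[tuple]:
    root = _xml_root(path)
    ns = {"g": _GPX_NS, "x": _GPX_TPX_NS}
    rows = []
    for tp in root.iterfind(".//g:trkpt", ns):
        time_el = tp.find("g:time", ns)
        if time_el is None or not time_el.text:
            raise ParseError(f"{path}: trkpt at line {tp.sourceline} lacks <time>")
        ele_el = tp.find("g:ele", ns)
        hr_el = tp.find("g:extensions/x:TrackPointExtension/x:hr", ns)
        rows.append(
            (
                _parse_naive_timestamp(time_el.text),
                float(tp.get("lat")) if tp.get("lat") is not None else math.nan,
                float(tp.get("lon")) if tp.get("lon") is not None else math.nan,
                float(ele_el.text) if ele_el is not None else math.nan,
                _screen_hr(float(hr_el.text)) if hr_el is not None else math.nan,
            )
        )
    return rows


def _read_gps_csv(path: Path, participant_id: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: malformed CSV: {exc}") from exc
    required = {"timestamp", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: CSV dialect missing columns {sorted(missing)}")
    out = pd.DataFrame(
        {
            "participant_id": df.get("participant_id", participant_id),
            "timestamp": pd.to_datetime(df["timestamp"]),
            "lat": pd.to_numeric(df["lat"], errors="coerce"),
            "lon": pd.to_numeric(df["lon"], errors="coerce"),
            "elevation": pd.to_numeric(df.get("elevation", np.nan), errors="coerce"),
            "heart_rate": pd.to_numeric(df.get("heart_rate", np.nan), errors="coerce"),
        }
    )
    bad_lat = out["lat"].abs() > 90
    bad_lon = out["lon"].abs() > 180
    if bad_lat.any() or bad_lon.any():
        n = int(bad_lat.sum() + bad_lon.sum())
        raise ValidationError(f"{path}: {n} fixes outside WGS84 coordinate bounds")
    hr = out["heart_rate"].to_numpy(float)
    lo, hi = HR_PLAUSIBLE
    hr[(hr <= lo) | (hr >= hi)] = np.nan
    out["heart_rate"] = hr
    return out


def write_gps_csv(track: pd.DataFrame, path) -> None:
    """Write a track in the package's CSV GPS dialect (lossless round trip)."""
    out = track.loc[:, GPS_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.10g")


def write_tcx(track: pd.DataFrame, path) -> None:
    """Write fixes as a single-lap TCX activity (one Trackpoint per fix)."""
    nsmap = {None: _TCX_NS}
    root = etree.Element("TrainingCenterDatabase", nsmap=nsmap)
    acts = etree.SubElement(root, "Activities")
    act = etree.SubElement(acts, "Activity", Sport="Walking")
    ts = pd.to_datetime(track["timestamp"])
    start = ts.iloc[0].strftime("%Y-%m-%dT%H:%M:%S") if len(track) else "1970-01-01T00:00:00"
    etree.SubElement(act, "Id").text = start
    lap = etree.SubElement(act, "Lap", StartTime=start)
    trk = etree.SubElement(lap, "Track")
    for row in track.itertuples(index=False):
        tp = etree.SubElement(trk, "Trackpoint")
        etree.SubElement(tp, "Time").text = pd.Timestamp(row.timestamp).strftime("%Y-%m-%dT%H:%M:%S")
        if not (math.isnan(row.lat) or math.isnan(row.lon)):
            pos = etree.SubElement(tp, "Position")
            etree.SubElement(pos, "LatitudeDegrees").text = repr(float(row.lat))
            etree.SubElement(pos, "LongitudeDegrees").text = repr(float(row.lon))
        if not math.isnan(row.elevation):
            etree.SubElement(tp, "AltitudeMeters").text = repr(float(row.elevation))
        if not math.isnan(row.heart_rate):
            hr = etree.SubElement(tp, "HeartRateBpm")
            etree.SubElement(hr, "Value").text = str(int(round(row.heart_rate)))
    etree.ElementTree(root).write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def write_gpx(track: pd.DataFrame, path) -> None:
    """Write fixes as a GPX track with Garmin heart-rate extensions."""
    nsmap = {None: _GPX_NS, "gpxtpx": _GPX_TPX_NS}
    root = etree.Element("gpx", nsmap=nsmap, version="1.1", creator="wearpa")
    trk = etree.SubElement(root, "trk")
    seg = etree.SubElement(trk, "trkseg")
    for row in track.itertuples(index=False):
        attrs = {}
        if not (math.isnan(row.lat) or math.isnan(row.lon)):
            attrs = {"lat": repr(float(row.lat)), "lon": repr(float(row.lon))}
        tp = etree.SubElement(seg, "trkpt", **attrs)
        if not math.isnan(row.elevation):
            etree.SubElement(tp, "ele").text = repr(float(row.elevation))
        etree.SubElement(tp, "time").text = pd.Timestamp(row.timestamp).strftime("%Y-%m-%dT%H:%M:%S")
        if not math.isnan(row.heart_rate):
            ext = etree.SubElement(tp, "extensions")
            tpx = etree.SubElement(ext, f"{{{_GPX_TPX_NS}}}TrackPointExtension")
            etree.SubElement(tpx, f"{{{_GPX_TPX_NS}}}hr").text = str(int(round(row.heart_rate)))
    etree.ElementTree(root).write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


# ---------------------------------------------------------------------------
# Daily wearable summaries


def read_daily_wearable(path) -> pd.DataFrame:
    """Read per-day wearable summaries (steps, resting heart rate).

    One row per (participant, date); duplicate dates for a participant and
    negative step counts are validation errors.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "date", "steps", "resting_heart_rate"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: wearable CSV missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    dup = df.duplicated(["participant_id", "date"])
    if dup.any():
        keys = df.loc[dup, ["participant_id", "date"]].to_records(index=False).tolist()
        raise ValidationError(f"{path}: duplicate participant-dates {keys[:5]}")
    if (df["steps"] < 0).any():
        raise ValidationError(f"{path}: negative step counts")
    return df


# ---------------------------------------------------------------------------
# Weather


_WEATHER_NUMERIC = ["tmin", "tmax", "tmean", "precip", "snow"]


def read_weather(path) -> pd.DataFrame:
    """Read daily weather-station records.

    Columns: ``station_id, lat, lon, date, tmin, tmax, tmean, precip, snow``
    (an optional ``daylight`` column is carried through).  Blank numeric
    fields stay missing — they are never coerced to zero.  A row whose
    minimum temperature exceeds its maximum is a validation error.
    """
    df = pd.read_csv(path)
    required = {"station_id", "date"} | set(_WEATHER_NUMERIC)
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: weather CSV missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    for col in _WEATHER_NUMERIC + (["daylight"] if "daylight" in df.columns else []):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = (df["tmin"] > df["tmax"]) & df["tmin"].notna() & df["tmax"].notna()
    if bad.any():
        raise ValidationError(f"{path}: {int(bad.sum())} rows with tmin > tmax")
    return df


# ---------------------------------------------------------------------------
# Participants


def read_participants(path) -> pd.DataFrame:
    """Read the participant roster.

    Columns: ``participant_id, age, sex, health, res_lat, res_lon`` with
    age ≥ 60, sex in {female, male} and self-rated health on 1–5.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "age", "sex", "health", "res_lat", "res_lon"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: roster CSV missing columns {sorted(missing)}")
    if (df["age"] < 60).any():
        raise ValidationError(f"{path}: participants below the study's 60-year minimum age")
    if not df["sex"].isin(["female", "male"]).all():
        raise ValidationError(f"{path}: sex must be 'female' or 'male'")
    if not df["health"].isin([1, 2, 3, 4, 5]).all():
        raise ValidationError(f"{path}: self-rated health must be an integer 1..5")
    return df


# ---------------------------------------------------------------------------
# Building footprints


@dataclass
class FootprintSet:
    """Building footprint polygons supporting bulk point-in-polygon queries."""

    ids: list
    geoms: list

    def __len__(self) -> int:
        return len(self.geoms)

    def total_area(self) -> float:
        """Sum of polygon areas in squared degrees (planar)."""
        return float(sum(g.area for g in self.geoms))

    def contains_xy(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Boolean mask: point inside or on the boundary of any footprint.

        Boundary points count as inside — conservative toward indoor so
        positional error does not inflate outdoor time.
        """
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        import shapely

        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        inside = np.zeros(lon.shape, bool)
        if not self.geoms or lon.size == 0:
            return inside
        # bounding-box prefilter per polygon, exact test on the candidates
        for geom in self.geoms:
            minx, miny, maxx, maxy = geom.bounds
            cand = np.flatnonzero(
                ~inside & (lon >= minx) & (lon <= maxx) & (lat >= miny) & (lat <= maxy)
            )
            if cand.size:
                inside[cand] = shapely.intersects_xy(geom, lon[cand], lat[cand])
        return inside


def read_footprints(path) -> FootprintSet:
    """Read building footprints from a GeoJSON FeatureCollection.

    Only Polygon/MultiPolygon geometries are accepted; unclosed rings and
    invalid (self-intersecting) geometries are rejected with their feature
    ids listed.
    """
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ParseError(f"{path}: expected a GeoJSON FeatureCollection")
    ids, geoms, bad = [], [], []
    for i, feat in enumerate(data.get("features", [])):
        fid = feat.get("id", feat.get("properties", {}).get("id", i))
        geom = feat.get("geometry") or {}
        if geom.get("type") not in ("Polygon", "MultiPolygon"):
            raise ValidationError(f"{path}: feature {fid} has non-polygon geometry {geom.get('type')!r}")
        if geom["type"] == "Polygon":
            rings = geom["coordinates"]
        else:
            rings = [r for poly in geom["coordinates"] for r in poly]
        closed = all(len(r) >= 4 and r[0] == r[-1] for r in rings)
        if not closed:
            bad.append(fid)
            continue
        g = shape(geom)
        if not g.is_valid:
            bad.append(fid)
            continue
        ids.append(fid)
        geoms.append(g)
    if bad:
        raise ValidationError(f"{path}: invalid footprint geometries (unclosed or self-intersecting): {bad}")
    return FootprintSet(ids=ids, geoms=geoms)


def write_footprints_geojson(footprints: FootprintSet, path) -> None:
    features = [
        {"type": "Feature", "id": fid, "properties": {"id": fid}, "geometry": mapping(geom)}
        for fid, geom in zip(footprints.ids, footprints.geoms)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
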