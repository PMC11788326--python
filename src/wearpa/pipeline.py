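"""End-to-end orchestration: ingest -> clean -> classify -> locate -> trips
-> weather merge -> models, with row-count accounting at every stage.

`process_cohort` runs the whole chain on in-memory inputs and returns all
intermediate artifacts plus a manifest; `run_pipeline` wraps it with file
I/O (a directory of GPS files plus the roster, wearable, weather and
footprint files) and writes the daily summaries, trips table, analysis
table, nine model tables and the run manifest to an output directory.
Inputs are never mutated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ingest, intensity, location, models, trajectory, trips, weather

__all__ = [
    "PipelineConfig",
    "process_cohort",
    "run_pipeline",
    "report_summary",
    "guideline_attainment",
    "WEEKLY_MVPA_GUIDELINE_MIN",
]

WEEKLY_MVPA_GUIDELINE_MIN = 150.0

#: Daily-summary variables reported by :func:`report_summary`, with labels.
_REPORT_VARS = [
    ("lpa_min", "LPA total time"),
    ("lpa_in_min", "LPA indoor time"),
    ("lpa_out_min", "LPA outdoor time"),
    ("mvpa_min", "MVPA total time"),
    ("mvpa_in_min", "MVPA indoor time"),
    ("mvpa_out_min", "MVPA outdoor time"),
    ("sb_min", "Sedentary time"),
    ("walk_out_min", "Time spent walking outdoors"),
]


@dataclass
class PipelineConfig:
    """Filesystem layout and knobs of one pipeline run."""

    input_dir: str
    out_dir: str
    gps_subdir: str = "gps"
    nonwear_gap_min: float = trajectory.NONWEAR_GAP_MIN
    min_day_hours: float = trips.MIN_DAY_HOURS
    min_valid_days: int = trips.MIN_VALID_DAYS
    fit_models: bool = True

    def content_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def process_cohort(
    gps: pd.DataFrame,
    wearable: pd.DataFrame,
    participants: pd.DataFrame,
    footprints: ingest.FootprintSet,
    weather_df: pd.DataFrame,
    nonwear_gap_min: float = trajectory.NONWEAR_GAP_MIN,
    min_day_hours: float = trips.MIN_DAY_HOURS,
    min_valid_days: int = trips.MIN_VALID_DAYS,
    fit_models: bool = True,
) -> dict:
    """Run the full analysis chain on in-memory inputs.

    Returns a dict with the cleaned track, per-fix labels, stops, trips,
    the participant-day ``daily`` summary, the merged ``analysis_table``,
    the nine fitted ``model_results`` and a ``manifest`` with per-stage
    row counts and itemized exclusions.
    """
    manifest: dict = {"stages": {}}

    n_raw = len(gps)
    clean = trajectory.clean_track(gps, gap_minutes=nonwear_gap_min)
    n_clean = len(clean)
    manifest["stages"]["clean"] = {
        "fixes_in": n_raw,
        "fixes_out": n_clean,
        "fixes_removed": n_raw - n_clean,
    }

    incl = trips.apply_inclusion(clean, min_hours=min_day_hours, min_days=min_valid_days)
    wear_all = incl.all_days
    n_dropped_part_days = int(
        wear_all["participant_id"].isin(incl.dropped_participants).sum()
        - incl.dropped_days["participant_id"].isin(incl.dropped_participants).sum()
    )
    manifest["stages"]["inclusion"] = {
        "days_in": len(wear_all),
        "days_short": len(incl.dropped_days),
        "participants_dropped": incl.dropped_participants,
        "days_lost_with_participants": n_dropped_part_days,
        "days_out": len(incl.kept_days),
    }
    assert len(incl.kept_days) + len(incl.dropped_days) + n_dropped_part_days == len(wear_all)

    track = incl.track
    labels = location.label_indoor_outdoor(track, footprints)
    stops, in_stop = trips.detect_stops(track)
    trip_table = trips.segment_trips(track, in_stop)
    walk_out = trips.outdoor_walking_minutes(track, trip_table, labels)

    profiles = {}
    for p in participants.itertuples(index=False):
        rhr = wearable.loc[wearable["participant_id"] == p.participant_id, "resting_heart_rate"]
        if len(rhr) == 0:
            continue
        profiles[p.participant_id] = intensity.build_profile(p.participant_id, p.age, rhr)

    daily_parts = []
    for pid, idx in track.groupby("participant_id", sort=True).indices.items():
        if pid not in profiles:
            continue
        prof = profiles[pid]
        sub = track.iloc[idx].reset_index(drop=True)
        tot = intensity.summarize_daily_intensity(sub, prof)
        loc = location.summarize_by_location(sub, prof, labels[idx])
        daily_parts.append(tot.merge(loc, on=["participant_id", "date"], validate="1:1"))
    daily = (
        pd.concat(daily_parts, ignore_index=True)
        if daily_parts
        else pd.DataFrame(columns=["participant_id", "date"])
    )
    daily = daily.merge(walk_out, on=["participant_id", "date"], how="left")
    daily["walk_out_min"] = daily["walk_out_min"].fillna(0.0)
    daily = daily.merge(
        wearable[["participant_id", "date"]].assign(
            date=pd.to_datetime(wearable["date"]),
            steps=wearable["steps"].to_numpy(),
        ),
        on=["participant_id", "date"],
        how="left",
        validate="1:1",
    )
    manifest["stages"]["daily_summary"] = {"participant_days": len(daily)}

    table = weather.nearest_station_merge(participants, weather_df, daily, wearable)
    assert len(table) == len(daily)  # merge preserves participant-days
    manifest["stages"]["analysis_table"] = {
        "rows": len(table),
        "incomplete_weather": int(table["incomplete"].sum()),
    }

    model_results = models.fit_all_models(table) if fit_models else {}
    manifest["stages"]["models"] = {
        k: {"n_obs": r.n_obs, "n_dropped": r.n_dropped, "singular": r.singular}
        for k, r in model_results.items()
    }
    return {
        "clean_track": track,
        "labels": labels,
        "stops": stops,
        "trips": trip_table,
        "daily": daily,
        "analysis_table": table,
        "model_results": model_results,
        "manifest": manifest,
        "inclusion": incl,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the pipeline from files and write all outputs.

    Reads GPS tracks from ``<input_dir>/<gps_subdir>/`` (TCX, GPX or the
    CSV dialect, one file per participant) plus ``participants.csv``,
    ``wearable.csv``, ``weather.csv`` and ``footprints.geojson``.
    Outputs land in ``config.out_dir``; the run manifest records the
    config hash and the per-stage row accounting.  Deterministic given
    identical inputs; inputs are never written to.
    """
    indir = Path(config.input_dir)
    gps_dir = indir / config.gps_subdir
    required = [
        indir / "participants.csv",
        indir / "wearable.csv",
        indir / "weather.csv",
        indir / "footprints.geojson",
    ]
    missing = [str(p) for p in required if not p.exists()]
    gps_files = sorted(p for p in gps_dir.glob("*") if p.suffix.lower() in (".tcx", ".gpx", ".csv")) if gps_dir.exists() else []
    if missing or not gps_files:
        raise FileNotFoundError(
            f"pipeline inputs missing before any stage ran: {missing or 'no GPS files'}"
        )

    participants = ingest.read_participants(indir / "participants.csv")
    wearable = ingest.read_daily_wearable(indir / "wearable.csv")
    weather_df = ingest.read_weather(indir / "weather.csv")
    footprints = ingest.read_footprints(indir / "footprints.geojson")
    gps = pd.concat(
        [ingest.read_gps_track(p) for p in gps_files], ignore_index=True
    )

    result = process_cohort(
        gps,
        wearable,
        participants,
        footprints,
        weather_df,
        nonwear_gap_min=config.nonwear_gap_min,
        min_day_hours=config.min_day_hours,
        min_valid_days=config.min_valid_days,
        fit_models=config.fit_models,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["daily"].to_csv(out / "daily_summary.csv", index=False)
    result["trips"].to_csv(out / "trips.csv", index=False)
    result["stops"].to_csv(out / "stops.csv", index=False)
    result["analysis_table"].to_csv(out / "analysis_table.csv", index=False)
    for k, r in result["model_results"].items():
        r.to_frame().to_csv(out / f"model_{k}_{r.outcome}.csv")
    summary, attain = report_summary(result["daily"])
    summary.to_csv(out / "summary_report.csv", index=False)
    manifest = dict(result["manifest"])
    manifest["config_hash"] = config.content_hash()
    manifest["inputs"] = {"gps_files": [p.name for p in gps_files]}
    manifest["guideline_attainment"] = attain
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out


def guideline_attainment(daily: pd.DataFrame) -> dict:
    """Share of participants whose mean weekly MVPA exceeds 150 minutes.

    Weekly MVPA per participant = mean daily MVPA minutes × 7.
    """
    per_person = daily.groupby("participant_id")["mvpa_min"].mean() * 7.0
    attainers = int((per_person > WEEKLY_MVPA_GUIDELINE_MIN).sum())
    n = int(per_person.size)
    return {
        "n_participants": n,
        "n_attainers": attainers,
        "percent": round(100.0 * attainers / n, 1) if n else float("nan"),
    }


def report_summary(daily: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Descriptive table in minutes and hours, plus guideline attainment.

    Means and SDs are taken over participant-days; hours are minutes/60
    rounded to two decimals, computed after the statistics (analysis
    stays on the minutes scale; hours are for readability only).
    """
    rows = []
    for col, label in _REPORT_VARS:
        if col not in daily.columns:
            continue
        vals = daily[col].dropna().to_numpy(float)
        mean_min = float(vals.mean()) if vals.size else float("nan")
        sd_min = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
        rows.append(
            {
                "variable": label,
                "mean_min": mean_min,
                "sd_min": sd_min,
                "mean_h": round(mean_min / 60.0, 2),
                "sd_h": round(sd_min / 60.0, 2),
            }
        )
    if "steps" in daily.columns:
        vals = daily["steps"].dropna().to_numpy(float)
        rows.append(
            {
                "variable": "Steps",
                "mean_min": float(vals.mean()) if vals.size else float("nan"),
                "sd_min": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                "mean_h": float("nan"),
                "sd_h": float("nan"),
            }
        )
    return pd.DataFrame(rows), guideline_attainment(daily)
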