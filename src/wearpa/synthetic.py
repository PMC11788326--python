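"""Synthetic cohort with known ground truth.

Two generators at different resolutions:

* :func:`simulate_cohort` builds a full device-level cohort — a village of
  building footprints, per-participant GPS fix sequences with heart rate,
  daily wearable summaries, weather stations — and writes every file
  format the ingest module reads.  Each participant-day is a schedule of
  behaviour blocks (home dwell, indoor activity, outdoor walks, gardening,
  bike rides, vehicle errands) whose planted minutes per intensity ×
  location, trip windows and transport modes are recorded as ground
  truth.  Device artifacts (jump fixes, missing heart rate, duplicate
  timestamps, mid-day non-wear gaps) are injected at configurable rates.

* :func:`simulate_panel` skips the device layer and draws participant-day
  outcomes directly from the random-intercept model with planted
  coefficients and variance components at the scale of the published
  tables.  It is the workhorse for parameter-recovery and power checks,
  where hundreds of replicate cohorts are needed.

Default configuration mirrors the study conditions: 40 participants aged
60+, 10 consecutive monitored days each, fixes every 1–5 s ("smart
recording": faster sampling while moving fast), roughly 12.7 h of daily
wear, and collection windows spread across a full year so the weather
series spans both freeze-thaw and tropical-night regimes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .ingest import FootprintSet, write_footprints_geojson, write_gps_csv, write_tcx

__all__ = [
    "SimConfig",
    "PlantedOutcome",
    "DEFAULT_PLANTED",
    "simulate_weather",
    "simulate_participants",
    "make_village",
    "simulate_day_trajectory",
    "simulate_heart_rate",
    "simulate_cohort",
    "simulate_cohort_frames",
    "simulate_panel",
    "CohortFrames",
]

# Village origin (approximately the study region's latitude band).
_LAT0, _LON0 = 49.88, -119.49
_M_PER_DEG_LAT = 111_320.0

# Heart-rate-reserve fractions each behaviour state targets.
_STATE_HRR = {
    "dwell": 0.10,
    "plaza_dwell": 0.10,
    "indoor_lpa": 0.30,
    "indoor_mvpa": 0.55,
    "garden": 0.30,
    "walk": 0.30,
    "brisk_walk": 0.55,
    "bike": 0.50,
    "drive": 0.10,
}

# (intensity, location) each state is planted as.
_STATE_CLASS = {
    "dwell": ("SB", "in"),
    "plaza_dwell": ("SB", "in"),
    "indoor_lpa": ("LPA", "in"),
    "indoor_mvpa": ("MVPA", "in"),
    "garden": ("LPA", "out"),
    "walk": ("LPA", "out"),
    "brisk_walk": ("MVPA", "out"),
    "bike": ("MVPA", "out"),
    "drive": ("SB", "out"),
}

# Sampling interval per state, seconds: the device records faster while
# moving fast, keeping consecutive-fix distances well under the 30 m
# cleaning screen (as a 1 Hz device would in a vehicle).
_STATE_DT = {"bike": 2.0, "drive": 1.0}


@dataclass
class SimConfig:
    """Study conditions and planted truth for the device-level generator."""

    seed: int = 0
    n_participants: int = 40
    n_days: int = 10
    fix_interval_s: float = 5.0
    age_range: tuple = (60, 85)
    female_ratio: float = 0.625
    health_probs: tuple = (0.01, 0.05, 0.24, 0.47, 0.23)
    # village layout
    n_building_rows: int = 5
    n_building_cols: int = 6
    building_w_m: float = 14.0
    building_h_m: float = 10.0
    street_pitch_m: float = 80.0
    n_stations: int = 2
    weather_regime: str = "mixed"  # mixed | winter | summer
    # planted daily-outcome effects (minutes scale)
    temp_outdoor_lpa_slope: float = 2.33  # min per °C of within-window temp deviation
    freeze_thaw_walk_shift: float = -11.57  # min on freeze-thaw days
    sex_indoor_lpa_shift: float = 62.86  # extra indoor LPA min/day for females
    age_slopes: dict = field(default_factory=lambda: {"walk_out_min": -1.0})
    hr_noise_sd: float = 5.0
    # artifact rates
    jump_rate: float = 0.0015  # per fix: displaced 100-500 m
    missing_hr_rate: float = 0.01  # per fix
    dup_ts_rate: float = 0.001  # per fix: duplicated timestamp
    nonwear_gap_prob: float = 0.5  # per day: one 65-85 min mid-day gap
    short_day_prob: float = 0.05  # per day: device started late -> under 9 h
    day_span_mean_min: float = 757.0  # waking span the device is worn (~12.7 h wear)
    day_span_sd_min: float = 70.0
    position_jitter_m: float = 1.2

    def __post_init__(self):
        for r in (self.jump_rate, self.missing_hr_rate, self.dup_ts_rate, self.nonwear_gap_prob):
            if not 0.0 <= r <= 1.0:
                raise ValueError("artifact rates must lie in [0, 1]")
        if self.fix_interval_s < 1.0:
            raise ValueError("fix_interval_s must be at least 1 s")


def _xy_to_lonlat(x, y):
    lat = _LAT0 + np.asarray(y, float) / _M_PER_DEG_LAT
    lon = _LON0 + np.asarray(x, float) / (_M_PER_DEG_LAT * np.cos(np.radians(_LAT0)))
    return lon, lat


def make_village(config: SimConfig) -> tuple[FootprintSet, np.ndarray, tuple]:
    """Rectangular buildings on a street grid, plus one distant 'plaza'.

    Returns the footprint set, the building centers in local meters, and
    the plaza center.
    """
    centers = []
    geoms, ids = [], []
    hw, hh = config.building_w_m / 2, config.building_h_m / 2
    for i in range(config.n_building_rows):
        for j in range(config.n_building_cols):
            cx, cy = j * config.street_pitch_m, i * config.street_pitch_m
            centers.append((cx, cy))
            lon, lat = _xy_to_lonlat(
                np.array([cx - hw, cx + hw, cx + hw, cx - hw, cx - hw]),
                np.array([cy - hh, cy - hh, cy + hh, cy + hh, cy - hh]),
            )
            geoms.append(Polygon(zip(lon, lat)))
            ids.append(f"B{i:02d}{j:02d}")
    plaza = (config.n_building_cols * config.street_pitch_m + 3000.0, 0.0)
    lon, lat = _xy_to_lonlat(
        np.array([plaza[0] - 25, plaza[0] + 25, plaza[0] + 25, plaza[0] - 25, plaza[0] - 25]),
        np.array([plaza[1] - 20, plaza[1] - 20, plaza[1] + 20, plaza[1] + 20, plaza[1] - 20]),
    )
    geoms.append(Polygon(zip(lon, lat)))
    ids.append("PLAZA")
    return FootprintSet(ids=ids, geoms=geoms), np.array(centers), plaza


def simulate_participants(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Roster: ages 60+, sex mix, self-rated health 1-5, home residences."""
    n = config.n_participants
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, n)
    sexes = np.where(rng.random(n) < config.female_ratio, "female", "male")
    health = rng.choice([1, 2, 3, 4, 5], size=n, p=config.health_probs)
    _, centers, _ = make_village(config)
    homes = rng.choice(len(centers), size=n, replace=n > len(centers))
    lon, lat = _xy_to_lonlat(centers[homes, 0], centers[homes, 1])
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:02d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "health": health,
            "res_lat": lat,
            "res_lon": lon,
            "home_idx": homes,
        }
    )


def _seasonal_tmean(doy: np.ndarray) -> np.ndarray:
    # Annual cycle of a warm-winter / hot-summer interior valley:
    # January mean near -2 °C, July near 22 °C.
    return 10.0 + 12.0 * np.sin(2.0 * np.pi * (doy - 105.0) / 365.25)


def simulate_weather(
    config: SimConfig, rng: np.random.Generator, dates: pd.DatetimeIndex
) -> pd.DataFrame:
    """Station-day weather over ``dates`` for each station.

    Seasonal sinusoid plus day-to-day noise; diurnal spread guarantees
    tmin ≤ tmean ≤ tmax.  Winter spells produce freeze-thaw days, summer
    heat produces tropical nights.
    """
    st_off = np.linspace(0.0, 1.0, config.n_stations)  # small inter-station bias
    sx = np.linspace(-500.0, 3500.0, config.n_stations)
    rows = []
    doy = dates.dayofyear.to_numpy(float)
    base = _seasonal_tmean(doy)
    shared = rng.normal(0.0, 3.5, len(dates))  # synoptic noise shared by stations
    for s in range(config.n_stations):
        tmean = base + shared + rng.normal(0.0, 0.6, len(dates)) + st_off[s]
        up = 5.0 + np.abs(rng.normal(0.0, 1.5, len(dates)))
        down = 5.0 + np.abs(rng.normal(0.0, 1.5, len(dates)))
        tmax = tmean + up
        tmin = tmean - down
        wet = rng.random(len(dates)) < 0.25
        precip = np.where(wet, rng.exponential(3.5, len(dates)), 0.0).round(1)
        snow = _snowpack(tmean, tmax, precip)
        lon, lat = _xy_to_lonlat(sx[s], -400.0)
        rows.append(
            pd.DataFrame(
                {
                    "station_id": f"S{s + 1}",
                    "lat": float(lat),
                    "lon": float(lon),
                    "date": dates.date,
                    "tmin": tmin.round(1),
                    "tmax": tmax.round(1),
                    "tmean": tmean.round(1),
                    "precip": precip,
                    "snow": snow,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _snowpack(tmean: np.ndarray, tmax: np.ndarray, precip: np.ndarray) -> np.ndarray:
    """Snow-on-ground level (cm) from accumulation/melt dynamics.

    Cold-day precipitation accumulates (~1 cm per mm of water), warm
    maxima melt the pack.  The level therefore carries day-to-day memory
    and precipitation's own randomness instead of being a deterministic
    transform of temperature.
    """
    level = 0.0
    out = np.empty(len(tmean))
    for i in range(len(tmean)):
        if tmean[i] < 0.5:
            level += 1.0 * precip[i]
        level -= 0.6 * max(tmax[i], 0.0)
        level = min(max(level, 0.0), 22.0)
        out[i] = round(level)
    return out


def _window_start(config: SimConfig, rng: np.random.Generator) -> pd.Timestamp:
    year0 = pd.Timestamp("2021-10-01")
    if config.weather_regime == "winter":
        lo, hi = 61, 140  # Dec-Feb
    elif config.weather_regime == "summer":
        lo, hi = 270, 350  # Jul-Sep
    else:
        lo, hi = 0, 355
    return year0 + pd.Timedelta(days=int(rng.integers(lo, hi + 1)))


def _path_fixes(waypoints: list[tuple], speed: float, dt: float, t0: float):
    """Positions every ``dt`` s along a waypoint polyline at constant speed."""
    pts = np.asarray(waypoints, float)
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = seglen.sum()
    duration = total / speed
    times = np.arange(0.0, duration, dt)
    s = times * speed
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = np.where(seglen[idx] > 0, (s - cum[idx]) / seglen[idx], 0.0)
    xy = pts[idx] + seg[idx] * frac[:, None]
    return xy, t0 + times


def _ar1_jitter(rng: np.random.Generator, n: int, sd: float, phi: float = 0.95) -> np.ndarray:
    """Slowly drifting positional error (AR(1) with stationary SD ``sd``).

    GPS error is strongly autocorrelated between nearby fixes; independent
    per-fix noise would make a stationary wearer appear to move at nearly
    the stop-detection speed threshold.
    """
    from scipy.signal import lfilter

    e = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), n)
    x0 = rng.normal(0.0, sd)
    out, _ = lfilter([1.0], [1.0, -phi], e, zi=[phi * x0])
    return out


class _DayPlanItem(NamedTuple):
    state: str
    minutes: float


def _plan_day(
    config,
    rng,
    participant,
    tmean_dev: float,
    freeze_thaw: int,
    walk_base: float = 45.0,
    garden_base: float = 30.0,
) -> list[_DayPlanItem]:
    """Draw one day's behaviour-block schedule with planted effects."""
    female = participant.sex == "female"
    age_c = participant.age - 72.0
    plan: list[_DayPlanItem] = [
        _DayPlanItem("dwell", float(rng.normal(60, 12))),
        _DayPlanItem(
            "indoor_lpa",
            float(
                np.clip(
                    rng.normal(60, 18) + (config.sex_indoor_lpa_shift if female else 0.0), 10, 240
                )
            ),
        ),
    ]
    if rng.random() < 0.6:
        plan.append(_DayPlanItem("indoor_mvpa", float(np.clip(rng.normal(50, 12), 15, 120))))
    plan.append(_DayPlanItem("dwell", float(rng.normal(70, 15))))
    # Gardening/yard time carries the within-window temperature slope.
    garden = garden_base + config.temp_outdoor_lpa_slope * tmean_dev + rng.normal(0, 8)
    if garden > 4.0:
        plan.append(_DayPlanItem("garden", float(min(garden, 150.0))))
    walk = (
        walk_base
        + config.freeze_thaw_walk_shift * freeze_thaw
        + config.age_slopes.get("walk_out_min", 0.0) * age_c
        + rng.normal(0, 8)
    )
    if walk > 4.0:
        plan.append(_DayPlanItem("walk", float(min(walk, 150.0))))
    plan.append(_DayPlanItem("dwell", float(rng.normal(90, 20))))
    # a daily brisk walk is a stable habit in this (deliberately active)
    # cohort; keeping it regular stops its on/off variance from swamping
    # the planted weather effects on the walking outcome
    plan.append(_DayPlanItem("brisk_walk", float(np.clip(rng.normal(45, 10), 15, 110))))
    if rng.random() < 0.25:
        plan.append(_DayPlanItem("bike", float(np.clip(rng.normal(20, 5), 8, 45))))
    if rng.random() < 0.5:
        plan.extend(
            [
                _DayPlanItem("drive", float(rng.uniform(8, 14))),
                _DayPlanItem("plaza_dwell", float(rng.normal(40, 8))),
                _DayPlanItem("drive", float(rng.uniform(8, 14))),
            ]
        )
    plan = [p for p in plan if p.minutes > 0]
    # The worn day span is set by wake/sleep (and occasionally by a device
    # started late), never by the activity draws themselves: idle home
    # time absorbs the slack.  Tying span to the activity sum would let
    # the nine-hour inclusion rule select on the planted outcomes.
    if rng.random() < config.short_day_prob:
        span = float(np.clip(rng.normal(420.0, 60.0), 300.0, 520.0))
    else:
        span = float(rng.normal(config.day_span_mean_min, config.day_span_sd_min))
    used = sum(p.minutes for p in plan)
    if used <= span - 20.0:
        plan.append(_DayPlanItem("dwell", span - used))
    else:  # short day: truncate the schedule at the span
        cut, acc = [], 0.0
        for p in plan:
            if acc + p.minutes >= span:
                cut.append(_DayPlanItem(p.state, max(span - acc, 1.0)))
                break
            cut.append(p)
            acc += p.minutes
        plan = cut
    # Separate consecutive moving blocks with a short home dwell so each
    # planted trip is bounded by a stop (a bike ride rolling straight into
    # a car trip would otherwise merge into one in-transit segment).
    moving = {"walk", "brisk_walk", "bike", "drive"}
    out: list[_DayPlanItem] = []
    for item in plan:
        if (
            out
            and item.state in moving
            and out[-1].state in moving
            and not (out[-1].state == "drive" and item.state == "drive")
        ):
            out.append(_DayPlanItem("dwell", float(rng.uniform(8.0, 14.0))))
        out.append(item)
    return out


def simulate_day_trajectory(
    config: SimConfig,
    rng: np.random.Generator,
    home_xy: tuple,
    plaza_xy: tuple,
    plan: list[_DayPlanItem],
    day_start: pd.Timestamp,
) -> tuple[pd.DataFrame, list[dict]]:
    """Fix positions/times (no heart rate yet) for one planned day.

    Returns the fixes and per-block truth records (state, start, end,
    scheduled minutes).  Stationary states jitter around a point; moving
    states follow street-corridor polylines at state-typical speeds, so a
    walk stays off building footprints by construction.
    """
    hx, hy = home_xy
    corridor_y = hy + config.building_h_m / 2 + 12.0  # clear of the home row
    vx = hx + config.street_pitch_m / 2  # vertical street east of home
    t = 0.0
    xs, ys, ts = [], [], []
    truth = []
    gap_after = None
    if rng.random() < config.nonwear_gap_prob:
        gap_after = rng.uniform(0.35, 0.6)  # fraction of blocks elapsed
        gap_minutes = rng.uniform(65.0, 85.0)
    total_blocks = len(plan)
    dt0 = config.fix_interval_s

    for bi, item in enumerate(plan):
        state, minutes = item.state, item.minutes
        dur = minutes * 60.0
        dt = _STATE_DT.get(state, dt0)
        if state in ("dwell", "indoor_lpa", "indoor_mvpa", "plaza_dwell", "garden"):
            if state == "plaza_dwell":
                cx, cy = plaza_xy
            elif state == "garden":
                cx, cy = hx, corridor_y
            else:
                cx, cy = hx, hy
            n = max(int(dur / dt), 1)
            jx = np.clip(_ar1_jitter(rng, n, config.position_jitter_m), -4.0, 4.0)
            jy = np.clip(_ar1_jitter(rng, n, config.position_jitter_m), -3.5, 3.5)
            bx, by = cx + jx, cy + jy
            bt = t + np.arange(n) * dt
        else:
            if state in ("walk", "brisk_walk", "bike"):
                speed = {
                    "walk": rng.uniform(1.0, 1.35),
                    "brisk_walk": rng.uniform(1.3, 1.5),
                    "bike": rng.uniform(3.5, 5.5),
                }[state]
                half = speed * dur / 2.0
                direction = 1.0 if rng.random() < 0.5 else -1.0
                out_pt = (hx + direction * half, corridor_y)
                waypoints = [(hx, corridor_y), out_pt, (hx, corridor_y)]
            else:  # drive
                speed = rng.uniform(9.0, 13.0)
                leg = speed * dur
                if bi + 1 < total_blocks and plan[bi + 1].state == "plaza_dwell":
                    waypoints = [(hx, corridor_y), (vx, corridor_y), (vx, plaza_xy[1]), plaza_xy]
                else:
                    waypoints = [plaza_xy, (vx, plaza_xy[1]), (vx, corridor_y), (hx, corridor_y)]
                # stretch the middle leg so the drive fills its scheduled time
                extra = leg - sum(
                    np.hypot(b[0] - a[0], b[1] - a[1])
                    for a, b in zip(waypoints[:-1], waypoints[1:])
                )
                if extra > 0:
                    waypoints.insert(2, (vx, waypoints[2][1] - extra / 2.0))
            xy, bt = _path_fixes(waypoints, speed, dt, t)
            bx = xy[:, 0] + _ar1_jitter(rng, len(xy), config.position_jitter_m)
            by = xy[:, 1] + _ar1_jitter(rng, len(xy), config.position_jitter_m)
        xs.append(bx)
        ys.append(by)
        ts.append(bt)
        truth.append(
            {
                "state": state,
                "start_s": t,
                "end_s": t + dur,
                "minutes": minutes,
                "intensity": _STATE_CLASS[state][0],
                "location": _STATE_CLASS[state][1],
            }
        )
        t += dur
        if gap_after is not None and bi == int(gap_after * total_blocks):
            t += gap_minutes * 60.0
            truth.append({"state": "nonwear_gap", "start_s": t - gap_minutes * 60.0,
                          "end_s": t, "minutes": gap_minutes,
                          "intensity": None, "location": None})

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    tt = np.concatenate(ts)
    lon, lat = _xy_to_lonlat(x, y)
    fixes = pd.DataFrame(
        {
            "timestamp": day_start + pd.to_timedelta(np.round(tt).astype(np.int64), unit="s"),
            "lat": lat,
            "lon": lon,
            "elevation": 350.0 + rng.normal(0.0, 1.0, len(x)).round(1),
        }
    )
    return fixes, truth


def simulate_heart_rate(
    rng: np.random.Generator,
    n_fixes_per_block: list[int],
    states: list[str],
    resting_hr: float,
    hrr: float,
    noise_sd: float,
) -> np.ndarray:
    """Heart rate per fix: resting + state fraction of HRR + Gaussian noise,
    truncated to the plausible (20, 250) bpm band."""
    parts = [
        np.full(n, resting_hr + _STATE_HRR[s] * hrr) for n, s in zip(n_fixes_per_block, states)
    ]
    hr = np.concatenate(parts) + rng.normal(0.0, noise_sd, sum(n_fixes_per_block))
    return np.clip(hr, 20.5, 249.5)


def _inject_artifacts(fixes: pd.DataFrame, config: SimConfig, rng: np.random.Generator):
    """Plant jump fixes, missing HR and duplicate timestamps; returns the
    fixes plus the indices planted (for oracle tests)."""
    n = len(fixes)
    jump = np.flatnonzero(rng.random(n) < config.jump_rate)
    if jump.size:
        ang = rng.uniform(0, 2 * np.pi, jump.size)
        r = rng.uniform(100.0, 500.0, jump.size)
        fixes.loc[jump, "lat"] += r * np.sin(ang) / _M_PER_DEG_LAT
        fixes.loc[jump, "lon"] += r * np.cos(ang) / (_M_PER_DEG_LAT * np.cos(np.radians(_LAT0)))
    miss = np.flatnonzero(rng.random(n) < config.missing_hr_rate)
    fixes.loc[miss, "heart_rate"] = np.nan
    dup = np.flatnonzero(rng.random(n) < config.dup_ts_rate)
    if dup.size:
        extra = fixes.iloc[dup].copy()
        extra["lat"] += rng.normal(0.0, 2e-5, dup.size)
        pieces, order = [], np.argsort(np.concatenate([np.arange(n), dup + 0.5]), kind="stable")
        fixes = pd.concat([fixes, extra], ignore_index=True).iloc[order].reset_index(drop=True)
    return fixes, {"jump": jump.tolist(), "missing_hr": miss.tolist(), "dup": dup.tolist()}


class CohortFrames(NamedTuple):
    gps: pd.DataFrame  # all participants' fixes, file order
    wearable: pd.DataFrame
    participants: pd.DataFrame
    weather: pd.DataFrame
    footprints: FootprintSet
    truth: dict


def simulate_cohort_frames(config: SimConfig | None = None) -> CohortFrames:
    """Generate the whole cohort in memory (see :func:`simulate_cohort`)."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    footprints, centers, plaza = make_village(config)
    participants = simulate_participants(config, rng)

    all_fixes, wearable_rows = [], []
    truth: dict = {
        "config": {k: v for k, v in asdict(config).items()},
        "planted_effects": {
            "temp_outdoor_lpa_slope": config.temp_outdoor_lpa_slope,
            "freeze_thaw_walk_shift": config.freeze_thaw_walk_shift,
            "sex_indoor_lpa_shift": config.sex_indoor_lpa_shift,
        },
        "days": {},
        "artifacts": {},
    }
    windows = {}
    for p in participants.itertuples(index=False):
        start = _window_start(config, rng)
        windows[p.participant_id] = pd.date_range(start, periods=config.n_days, freq="D")
    all_dates = pd.DatetimeIndex(
        sorted({d for w in windows.values() for d in w})
    )
    weather = simulate_weather(config, rng, all_dates)
    w1 = weather[weather["station_id"] == "S1"].set_index("date")

    for p in participants.itertuples(index=False):
        resting = float(rng.normal(62.0, 6.0))
        hrr = (220.0 - p.age) - resting
        home = tuple(centers[p.home_idx])
        # stable person-level habits give the outcomes a realistic
        # between-person variance share (non-trivial ICC)
        walk_base = float(rng.normal(45.0, 10.0))
        garden_base = float(rng.normal(30.0, 6.0))
        pid_fixes = []
        dates = windows[p.participant_id]
        tdev = w1.loc[dates.date, "tmean"].to_numpy(float)
        tdev = tdev - tdev.mean()  # within-window temperature deviation
        for di, day in enumerate(dates):
            ft = int(
                w1.loc[day.date(), "tmin"] <= 0.0 and w1.loc[day.date(), "tmax"] > 0.0
            )
            plan = _plan_day(config, rng, p, tdev[di], ft, walk_base, garden_base)
            day_start = day + pd.Timedelta(minutes=int(rng.integers(7 * 60 + 30, 8 * 60 + 30)))
            fixes, block_truth = simulate_day_trajectory(config, rng, home, plaza, plan, day_start)
            counts, states = [], []
            pos = 0
            for b in block_truth:
                if b["state"] == "nonwear_gap":
                    continue
                nb = int(np.sum((fixes["timestamp"] - day_start).dt.total_seconds().between(
                    b["start_s"], b["end_s"] - 1e-9)))
                counts.append(nb)
                states.append(b["state"])
                pos += nb
            # guard against rounding at block edges
            counts[-1] += len(fixes) - sum(counts)
            fixes["heart_rate"] = simulate_heart_rate(
                rng, counts, states, resting, hrr, config.hr_noise_sd
            )
            pid_fixes.append(fixes)
            truth["days"][f"{p.participant_id}|{day.date().isoformat()}"] = {
                "blocks": block_truth,
                "freeze_thaw": ft,
                "tmean_dev": float(tdev[di]),
            }
            walk_min = sum(b["minutes"] for b in block_truth if b["state"] in ("walk", "brisk_walk"))
            steps = 105.0 * walk_min + rng.normal(3000.0, 800.0)
            wearable_rows.append(
                {
                    "participant_id": p.participant_id,
                    "date": day.date(),
                    "steps": int(max(steps, 0.0)),
                    "resting_heart_rate": round(resting + rng.normal(0.0, 1.5), 1),
                }
            )
        pf = pd.concat(pid_fixes, ignore_index=True)
        pf, planted = _inject_artifacts(pf, config, rng)
        pf.insert(0, "participant_id", p.participant_id)
        truth["artifacts"][p.participant_id] = planted
        all_fixes.append(pf)

    gps = pd.concat(all_fixes, ignore_index=True)
    wearable = pd.DataFrame(wearable_rows)
    return CohortFrames(
        gps=gps,
        wearable=wearable,
        participants=participants.drop(columns=["home_idx"]),
        weather=weather,
        footprints=footprints,
        truth=truth,
    )


def simulate_cohort(
    config: SimConfig | None = None, outdir=None, gps_format: str = "csv"
) -> tuple[dict, dict]:
    """Generate the cohort and write every input file the pipeline reads.

    Writes ``gps/<pid>.csv`` (or ``.tcx``), ``wearable.csv``,
    ``participants.csv``, ``weather.csv``, ``footprints.geojson`` and
    ``ground_truth.json`` under ``outdir``.  Returns ``(paths, truth)``.
    The same seed yields byte-identical files.
    """
    config = config or SimConfig()
    outdir = Path(outdir) if outdir is not None else Path("scratch/cohort")
    frames = simulate_cohort_frames(config)
    gps_dir = outdir / "gps"
    gps_dir.mkdir(parents=True, exist_ok=True)
    writer = {"csv": write_gps_csv, "tcx": write_tcx}[gps_format]
    gps_paths = {}
    for pid, g in frames.gps.groupby("participant_id", sort=True):
        path = gps_dir / f"{pid}.{gps_format}"
        writer(g.reset_index(drop=True), path)
        gps_paths[pid] = str(path)
    frames.wearable.to_csv(outdir / "wearable.csv", index=False)
    frames.participants.to_csv(outdir / "participants.csv", index=False, float_format="%.8f")
    frames.weather.to_csv(outdir / "weather.csv", index=False)
    write_footprints_geojson(frames.footprints, outdir / "footprints.geojson")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(frames.truth, fh, indent=1, default=str)
    paths = {
        "gps": gps_paths,
        "wearable": str(outdir / "wearable.csv"),
        "participants": str(outdir / "participants.csv"),
        "weather": str(outdir / "weather.csv"),
        "footprints": str(outdir / "footprints.geojson"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    return paths, frames.truth


# ---------------------------------------------------------------------------
# Panel-level generator


@dataclass(frozen=True)
class PlantedOutcome:
    """One outcome drawn from the random-intercept model with known truth.

    ``coefs`` maps design-term names (as in ``models.DEFAULT_PREDICTORS``)
    to fixed-effect values; unlisted terms are zero.  ``sigma2`` and
    ``tau00`` are the residual and intercept variances.
    """

    name: str
    intercept: float
    coefs: dict
    sigma2: float
    tau00: float


#: Planted outcomes at the scale of the study's reported models: the
#: within-person temperature slope on outdoor LPA and the freeze-thaw
#: shift on outdoor walking, with matching variance components.
DEFAULT_PLANTED = (
    PlantedOutcome(
        name="lpa_out_min",
        intercept=74.49,
        coefs={"tmean_daily": 2.33},
        sigma2=2167.65,
        tau00=1059.45,
    ),
    PlantedOutcome(
        name="walk_out_min",
        intercept=28.15,
        coefs={"freeze_thaw": -11.57},
        sigma2=882.87,
        tau00=310.38,
    ),
)


def simulate_panel(
    seed: int,
    n_persons: int = 40,
    n_days: int = 10,
    outcomes: tuple = DEFAULT_PLANTED,
    regime: str = "mixed",
) -> tuple[pd.DataFrame, dict]:
    """Participant-day analysis table drawn directly from the model.

    Weather covariates follow the seasonal generator (each participant
    gets a contiguous 10-day window somewhere in the year), demographics
    follow the cohort distributions, and each planted outcome is

        y_ij = intercept + x_ij' beta + u_i + e_ij,

    where the design terms are built exactly as the fitting code builds
    them (within/between centering on the realized sample).  Returns the
    table and the truth dict.
    """
    from .models import DEFAULT_PREDICTORS, WEATHER_PAIRS, center_within_between

    rng = np.random.default_rng(seed)
    config = SimConfig(seed=seed, n_participants=n_persons, n_days=n_days, weather_regime=regime)
    participants = simulate_participants(config, rng)

    rows = []
    for p in participants.itertuples(index=False):
        start = _window_start(config, rng)
        dates = pd.date_range(start, periods=n_days, freq="D")
        doy = dates.dayofyear.to_numpy(float)
        tmean = _seasonal_tmean(doy) + rng.normal(0.0, 3.5, n_days)
        up = 5.0 + np.abs(rng.normal(0.0, 1.5, n_days))
        down = 5.0 + np.abs(rng.normal(0.0, 1.5, n_days))
        wet = rng.random(n_days) < 0.25
        precip = np.where(wet, rng.exponential(3.5, n_days), 0.0)
        snow = _snowpack(tmean, tmean + up, precip)
        daylight = 12.0 + 4.2 * np.sin(2.0 * np.pi * (doy - 81.0) / 365.25)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": p.participant_id,
                    "date": dates.date,
                    "tmean": tmean,
                    "tmin": tmean - down,
                    "tmax": tmean + up,
                    "precip": precip,
                    "snow": snow,
                    "daylight": daylight,
                    "freeze_thaw": ((tmean - down <= 0.0) & (tmean + up > 0.0)).astype(int),
                    "tropical_night": (tmean - down >= 20.0).astype(int),
                    "study_day": np.arange(1, n_days + 1),
                    "weekend": (dates.dayofweek >= 5).astype(int),
                    "age": float(p.age),
                    "sex_female": int(p.sex == "female"),
                    "health": float(p.health),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)

    g = table["participant_id"]
    design = pd.DataFrame(index=table.index)
    for v in WEATHER_PAIRS:
        daily, overall = center_within_between(table[v], g)
        design[f"{v}_daily"] = daily
        design[f"{v}_overall"] = overall
    design["freeze_thaw"] = table["freeze_thaw"].astype(float)
    design["tropical_night"] = table["tropical_night"].astype(float)
    design["study_day"] = table["study_day"].astype(float)
    design["age_c"] = table["age"] - table.groupby("participant_id")["age"].first().mean()
    design["sex_female"] = table["sex_female"].astype(float)
    design["health_c"] = table["health"] - table.groupby("participant_id")["health"].first().mean()
    design["weekend"] = table["weekend"].astype(float)

    pid_codes = pd.factorize(table["participant_id"])[0]
    truth = {"outcomes": {}}
    for spec in outcomes:
        beta = np.array([spec.coefs.get(t, 0.0) for t in DEFAULT_PREDICTORS])
        mu = spec.intercept + design[DEFAULT_PREDICTORS].to_numpy() @ beta
        u = rng.normal(0.0, np.sqrt(spec.tau00), n_persons)
        e = rng.normal(0.0, np.sqrt(spec.sigma2), len(table))
        table[spec.name] = mu + u[pid_codes] + e
        truth["outcomes"][spec.name] = {
            "intercept": spec.intercept,
            "coefs": dict(spec.coefs),
            "sigma2": spec.sigma2,
            "tau00": spec.tau00,
        }
    return table, truth
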