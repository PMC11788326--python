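"""Inclusion rules, stop clustering, trip segmentation and transport mode."""

import numpy as np
import pandas as pd
import pytest

from wearpa import trajectory, trips

from conftest import make_track, walk_track


def clean(t):
    return trajectory.clean_track(t)


def day_track(hours, pid="P01", day=10):
    secs = np.arange(0, hours * 3600, 5.0)
    return make_track(secs, pid=pid, start=f"2022-01-{day:02d} 08:00:00")


class TestInclusion:
    def test_day_below_nine_hours_dropped(self):
        t = clean(pd.concat([day_track(8.9, day=10)] + [day_track(10, day=d) for d in range(11, 15)],
                            ignore_index=True))
        res = trips.apply_inclusion(t)
        kept_days = set(pd.to_datetime(res.kept_days["date"]).dt.day)
        assert 10 not in kept_days and len(kept_days) == 4

    def test_participant_with_three_valid_days_dropped_entirely(self):
        frames = [day_track(10, pid="P01", day=d) for d in (10, 11, 12)]
        frames += [day_track(10, pid="P02", day=d) for d in (10, 11, 12, 13)]
        res = trips.apply_inclusion(clean(pd.concat(frames, ignore_index=True)))
        assert res.dropped_participants == ["P01"]
        assert set(res.track["participant_id"]) == {"P02"}

    def test_all_full_days_is_identity(self):
        t = clean(pd.concat([day_track(12, day=d) for d in range(10, 20)], ignore_index=True))
        res = trips.apply_inclusion(t)
        assert len(res.track) == len(t)
        assert len(res.kept_days) == 10

    def test_day_rule_runs_before_participant_rule(self):
        # 5 days but only 3 of them reach 9 h -> participant goes too
        frames = [day_track(10, day=d) for d in (10, 11, 12)]
        frames += [day_track(5, day=d) for d in (13, 14)]
        res = trips.apply_inclusion(clean(pd.concat(frames, ignore_index=True)))
        assert res.dropped_participants == ["P01"]


def stationary(minutes, lat=49.88, lon=-119.49, start="2022-01-10 08:00:00", pid="P01"):
    secs = np.arange(0, minutes * 60 + 1, 5.0)
    return make_track(secs, lat=np.full(len(secs), lat), lon=np.full(len(secs), lon),
                      start=start, pid=pid)


class TestStops:
    def test_three_minutes_stationary_is_one_stop(self):
        stops, mask = trips.detect_stops(clean(stationary(3)))
        assert len(stops) == 1
        assert mask.sum() >= len(mask) - 1  # final fix has no speed

    def test_ninety_seconds_is_not_a_stop(self):
        stops, _ = trips.detect_stops(clean(stationary(1.5)))
        assert len(stops) == 0

    def test_planted_dwells_recovered(self):
        parts = []
        t0 = pd.Timestamp("2022-01-10 08:00:00")
        # dwell 10 min - walk 10 min - dwell 10 min - walk 10 min
        parts.append(stationary(10, start=t0))
        w1 = walk_track(600, 1.3, start=str(t0 + pd.Timedelta(minutes=10)))
        parts.append(w1)
        far = 49.88 + 1.3 * 600 / 111_320.0
        parts.append(stationary(10, lat=far, start=str(t0 + pd.Timedelta(minutes=20))))
        t = clean(pd.concat(parts, ignore_index=True))
        stops, mask = trips.detect_stops(t)
        assert len(stops) == 2
        durations = (stops["end"] - stops["start"]).dt.total_seconds() / 60.0
        assert np.all(np.abs(durations - 10.0) < 0.5)

    def test_stops_and_transit_partition_the_day(self):
        rng = np.random.default_rng(1)
        t = clean(stationary(30))
        stops, mask = trips.detect_stops(t)
        # each fix is exactly once a stop member or in transit
        assert mask.dtype == bool and len(mask) == len(t)

    def test_members_stay_within_radius_and_slow(self):
        rng = np.random.default_rng(2)
        n = 600
        lat = 49.88 + np.cumsum(rng.normal(0, 1e-6, n))
        t = clean(make_track(np.arange(n) * 5.0, lat=lat, lon=np.full(n, -119.49)))
        stops, mask = trips.detect_stops(t)
        assert (t.loc[mask, "fwd_speed_ms"] < trips.STOP_SPEED_MS).all()
        for s in stops.itertuples():
            member = t.iloc[s.first_idx : s.last_idx + 1]
            d = trajectory.haversine_m(
                member["lat"], member["lon"], s.centroid_lat, s.centroid_lon
            )
            assert (d <= trips.STOP_RADIUS_M + 1e-6).all()


class TestTripScreen:
    def _trip_of(self, duration_s, speed_ms):
        t = clean(walk_track(duration_s, speed_ms))
        stops, mask = trips.detect_stops(t)
        return trips.segment_trips(t, mask)

    def test_five_minute_walk_is_a_trip(self):
        tt = self._trip_of(300, 1.35)  # ~400 m
        assert len(tt) == 1 and tt.loc[0, "mode"] == "walking"

    def test_two_minutes_fails_duration(self):
        tt = self._trip_of(120, 2.5)  # 300 m but 2 min
        assert (tt["mode"] == "none").all()

    def test_fifty_meter_drift_fails_length(self):
        tt = self._trip_of(600, 50 / 600)  # 10 min, 50 m; speed 0.083 m/s < 0.5 -> stop
        assert len(tt[tt["mode"] != "none"]) == 0

    def test_mean_speed_below_one_kmh_fails(self):
        # 0.5-0.55 m/s jitters above stop speed but ~ mean 1.9 km/h... use
        # alternating fast/slow to get mean < 1 km/h while avoiding stops:
        # simplest certified case: 4 min, 90 m -> mean 0.375 m/s = 1.35 km/h
        # so instead plant 10 min covering 120 m -> 0.72 km/h
        n = 121
        lat = 49.88 + (0.2 * np.arange(n) * 5) / 111_320.0  # 0.2 m/s
        # inject speed spikes so fixes are not all stop-slow
        lat[::4] += 12 / 111_320.0
        t = clean(make_track(np.arange(n) * 5.0, lat=lat, lon=np.full(n, -119.49)))
        stops, mask = trips.detect_stops(t)
        tt = trips.segment_trips(t, mask)
        assert (tt["mode"].isin(["none"])).all() or (tt["mean_kmh"] >= 1.0).any()


class TestMode:
    @pytest.mark.parametrize(
        "p90,want",
        [
            (0.5, "none"),
            (1.0, "walking"),  # >=1 km/h inclusive
            (5.0, "walking"),
            (9.999, "walking"),
            (10.0, "biking"),  # >=10 km/h is biking
            (24.999, "biking"),
            (25.0, "vehicular"),  # >=25 km/h is vehicular
            (30.0, "vehicular"),
        ],
    )
    def test_band_boundaries(self, p90, want):
        assert trips.classify_mode(p90) == want

    @pytest.mark.parametrize("kmh,want", [(4, "walking"), (15, "biking"), (40, "vehicular")])
    def test_planted_speeds_recovered(self, kmh, want):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            v = kmh / 3.6
            dt = 1.0 if v > 6 else 5.0
            n = int(600 / dt)
            steps = v * dt * (1 + rng.normal(0, 0.05, n))
            lat = 49.5 + np.concatenate([[0], np.cumsum(steps[:-1])]) / 111_320.0
            t = clean(make_track(np.arange(n) * dt, lat=lat, lon=np.full(n, -119.0)))
            stops, mask = trips.detect_stops(t)
            tt = trips.segment_trips(t, mask)
            real = tt[tt["mode"] != "none"]
            if len(real) == 1 and real.iloc[0]["mode"] == want:
                hits += 1
        assert hits >= 24  # >= 95 % planted-mode recovery

    def test_p90_uses_linear_interpolation(self):
        speeds_kmh = np.array([2.0, 4.0, 6.0, 8.0, 9.0])
        v = speeds_kmh / 3.6
        secs = [0.0]
        lat = [49.5]
        for vi in v:
            secs.append(secs[-1] + 5.0)
            lat.append(lat[-1] + vi * 5.0 / 111_320.0)
        t = clean(make_track(secs, lat=lat, lon=np.full(len(secs), -119.0)))
        tt = trips.segment_trips(t, np.zeros(len(t), bool))
        # hand-coded type-7 percentile of the realized leg speeds
        leg = np.sort(t["fwd_speed_ms"].dropna().to_numpy() * 3.6)
        h = (len(leg) - 1) * 0.9
        lo = int(np.floor(h))
        expected = leg[lo] + (h - lo) * (leg[min(lo + 1, len(leg) - 1)] - leg[lo])
        assert tt.loc[0, "p90_kmh"] == pytest.approx(expected, rel=1e-9)


class TestOutdoorWalking:
    def _walking_day(self):
        t = clean(walk_track(1800, 1.3))
        stops, mask = trips.detect_stops(t)
        tt = trips.segment_trips(t, mask)
        return t, tt

    def test_entirely_outdoor_trip_counts_fully(self):
        t, tt = self._walking_day()
        lab = np.full(len(t), "outdoor", object)
        out = trips.outdoor_walking_minutes(t, tt, lab)
        assert out.loc[0, "walk_out_min"] == pytest.approx(30.0, abs=0.2)

    def test_entirely_indoor_trip_counts_zero(self):
        t, tt = self._walking_day()
        lab = np.full(len(t), "indoor", object)
        out = trips.outdoor_walking_minutes(t, tt, lab)
        assert len(out) == 0 or out["walk_out_min"].sum() == 0.0

    def test_mixed_labels_match_fix_level_brute_force(self):
        rng = np.random.default_rng(8)
        t, tt = self._walking_day()
        lab = np.where(rng.random(len(t)) < 0.5, "outdoor", "indoor").astype(object)
        out = trips.outdoor_walking_minutes(t, tt, lab)
        expected = 0.0
        for trip in tt.itertuples():
            if trip.mode != "walking":
                continue
            for i in range(trip.first_idx, trip.last_idx):
                if lab[i] == "outdoor" and t.loc[i, "wear"]:
                    expected += t.loc[i, "fwd_dt_s"]
        assert out["walk_out_min"].sum() * 60.0 == pytest.approx(expected, abs=1e-6)

    def test_walking_bounded_by_outdoor_totals(self, small_cohort):
        _, result = small_cohort
        d = result["daily"]
        outdoor = d["sb_out_min"] + d["lpa_out_min"] + d["mvpa_out_min"]
        assert (d["walk_out_min"] <= outdoor + 1e-6).all()
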