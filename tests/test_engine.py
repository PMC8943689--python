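"""Decision-engine rules: weather suitability, inactivity, time windows,
POI radii and the full decision function."""

import itertools
from datetime import datetime, timedelta

import numpy as np
import pytest

from deskbreak.engine import (
    CATEGORIES,
    EngineConfig,
    GeoPoint,
    Poi,
    UnknownForecastError,
    WeatherObservation,
    classify_weather,
    decide,
    eligible_pois,
    haversine_m,
    is_inactive,
    resolve_time_window,
)
from deskbreak.simulate import WORKPLACE, _offset


class TestWeather:
    @pytest.mark.parametrize(
        "temp,hum,forecast,expected",
        [
            (25.0, 50.0, "sunny", True),
            (40.0, 50.0, "sunny", False),     # above the 35 C ceiling
            (13.0, 89.9, "cloudy", True),     # both bounds just inside
            (35.0, 50.0, "clear skies", True),
            (12.9, 50.0, "sunny", False),
            (20.0, 90.0, "sunny", False),     # humidity bound is strict
            (20.0, 30.0, "rainy", False),
            (20.0, 30.0, "thunderstorm", False),
        ],
    )
    def test_classification(self, cfg, temp, hum, forecast, expected):
        assert classify_weather(WeatherObservation(temp, hum, forecast), cfg) is expected

    def test_unknown_forecast_named_in_error(self, cfg):
        with pytest.raises(UnknownForecastError, match="drizzle"):
            classify_weather(WeatherObservation(20.0, 50.0, "drizzle"), cfg)

    def test_agrees_with_bruteforce_recheck(self, cfg):
        """1,000 random observations against a literal re-check of the three
        suitability conditions."""
        rng = np.random.default_rng(42)
        labels = sorted(cfg.suitable_forecasts | cfg.unsuitable_forecasts)
        for _ in range(1000):
            obs = WeatherObservation(
                float(rng.uniform(-5, 50)),
                float(rng.uniform(0, 100)),
                labels[int(rng.integers(len(labels)))],
            )
            oracle = (
                13.0 <= obs.temperature <= 35.0
                and obs.humidity < 90.0
                and obs.forecast in {"clear skies", "sunny", "cloudy"}
            )
            assert classify_weather(obs, cfg) == oracle

    def test_humidity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            WeatherObservation(20.0, 101.0, "sunny")


class TestInactivity:
    @pytest.mark.parametrize("steps,expected", [(0, True), (66, True), (67, False), (500, False)])
    def test_threshold(self, cfg, steps, expected):
        assert is_inactive(steps, cfg) is expected

    def test_negative_steps_rejected(self, cfg):
        with pytest.raises(ValueError):
            is_inactive(-1, cfg)


class TestTimeWindow:
    @pytest.mark.parametrize(
        "hh,mm,expected",
        [
            (12, 15, "pre_lunch"),        # 15 min before 12:30 lunch
            (12, 0, "pre_lunch"),         # lead boundary, inclusive
            (12, 30, "generic"),          # lunch itself is out of the window
            (15, 45, "pre_endofwork"),    # 45 min before 16:30
            (16, 30, "generic"),
            (21, 30, "pre_endofday"),
            (10, 0, "generic"),
        ],
    )
    def test_workday_windows(self, cfg, schedule, hh, mm, expected):
        now = datetime(2021, 12, 5, hh, mm)  # Sunday = workday (Sun-Thu week)
        assert resolve_time_window(now, schedule, cfg) == expected

    def test_weekend_drops_work_windows(self, cfg, schedule):
        saturday = datetime(2021, 12, 4, 12, 15)
        assert resolve_time_window(saturday, schedule, cfg) == "generic"
        assert resolve_time_window(saturday.replace(hour=21, minute=30), schedule, cfg) == "pre_endofday"


class TestHaversine:
    def test_identity(self):
        p = GeoPoint(25.3, 51.5)
        assert haversine_m(p, p) == 0.0

    def test_one_degree_of_latitude(self):
        d = haversine_m(GeoPoint(0, 0), GeoPoint(1, 0))
        assert d == pytest.approx(111_195, abs=5)

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = GeoPoint(float(rng.uniform(-89, 89)), float(rng.uniform(-179, 179)))
            b = GeoPoint(float(rng.uniform(-89, 89)), float(rng.uniform(-179, 179)))
            assert haversine_m(a, b) == pytest.approx(haversine_m(b, a))
            assert haversine_m(a, b) >= 0


class TestEligiblePois:
    @pytest.mark.parametrize(
        "window,dist,included",
        [
            ("generic", 400, True),
            ("generic", 600, False),
            ("pre_lunch", 1400, True),
            ("pre_lunch", 1600, False),
            ("pre_endofwork", 5900, True),
            ("pre_endofwork", 6100, False),
        ],
    )
    def test_window_radii(self, cfg, make_context, window, dist, included):
        poi = Poi("Target", "park", _offset(WORKPLACE, dist, 45))
        ctx = make_context(pois=(poi,))
        got = eligible_pois(ctx, window, cfg)
        assert (poi in got) is included

    def test_sorted_by_distance_then_name(self, cfg, make_context):
        pois = (
            Poi("B-far", "park", _offset(WORKPLACE, 450, 0)),
            Poi("Z-near", "gym", _offset(WORKPLACE, 200, 90)),
            Poi("A-near", "mall", _offset(WORKPLACE, 200, 90)),
        )
        got = eligible_pois(make_context(pois=pois), "generic", cfg)
        assert [p.name for p in got] == ["A-near", "Z-near", "B-far"]


class TestDecide:
    def test_active_user_no_fire(self, cfg, make_context):
        d = decide(make_context(trailing_steps=500), None, cfg)
        assert not d.fire and d.category_id is None

    def test_prelunch_suitable_with_restaurant(self, cfg, make_context):
        ctx = make_context(now=datetime(2021, 12, 5, 12, 10))
        d = decide(ctx, None, cfg)
        assert d.fire and d.window == "pre_lunch" and d.category_id == "lunch-walk-out"

    def test_generic_unsuitable_weather_is_indoor(self, cfg, make_context):
        ctx = make_context(weather=WeatherObservation(20.0, 50.0, "rainy"))
        assert decide(ctx, None, cfg).category_id == "generic-indoor"
        ctx2 = make_context(weather=WeatherObservation(20.0, 50.0, "rainy"), pois=())
        assert decide(ctx2, None, cfg).category_id == "generic-stretch"

    def test_cooldown_suppresses(self, cfg, make_context):
        ctx = make_context()
        recent = ctx.now - timedelta(minutes=10)
        assert not decide(ctx, recent, cfg).fire
        stale = ctx.now - timedelta(minutes=40)
        assert decide(ctx, stale, cfg).fire

    def test_deterministic(self, cfg, make_context):
        ctx = make_context(now=datetime(2021, 12, 5, 15, 50))
        assert decide(ctx, None, cfg) == decide(ctx, None, cfg)

    def test_all_64_tailoring_combinations_valid(self, cfg, make_context, schedule):
        """Every {active} x {window} x {weather} x {POIs} x {goal} combination
        yields a consistent decision and a known category when firing."""
        window_times = {
            "pre_lunch": datetime(2021, 12, 5, 12, 10),
            "pre_endofwork": datetime(2021, 12, 5, 15, 45),
            "pre_endofday": datetime(2021, 12, 5, 21, 30),
            "generic": datetime(2021, 12, 5, 10, 0),
        }
        seen = set()
        for inactive, wname, suitable, has_poi, goal_met in itertools.product(
            [True, False], window_times, [True, False], [True, False], [True, False]
        ):
            ctx = make_context(
                now=window_times[wname],
                trailing_steps=0 if inactive else 500,
                weather=WeatherObservation(24.0, 50.0, "sunny" if suitable else "rainy"),
                pois=(Poi("P", "park", _offset(WORKPLACE, 300, 10)),) if has_poi else (),
                steps_today=9000 if goal_met else 3000,
                step_goal=8000,
            )
            d = decide(ctx, None, cfg)
            assert d.window == wname
            assert d.weather_suitable is suitable
            assert set(d.eligible_pois) <= set(ctx.pois)
            if inactive:
                assert d.fire and d.category_id in CATEGORIES
                seen.add(d.category_id)
            else:
                assert not d.fire and d.category_id is None
        assert len(seen) >= 10  # the tree is exercised broadly


class TestConfig:
    def test_inverted_temp_range_rejected(self):
        with pytest.raises(ValueError):
            EngineConfig(temp_range=(35.0, 13.0))

    def test_overlapping_forecast_sets_rejected(self):
        with pytest.raises(ValueError):
            EngineConfig(
                suitable_forecasts=frozenset({"sunny", "windy"}),
                unsuitable_forecasts=frozenset({"windy"}),
            )

    def test_yaml_round_trip(self, tmp_path, cfg):
        path = tmp_path / "engine.yaml"
        cfg.to_yaml(path)
        assert EngineConfig.from_yaml(path) == cfg
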