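"""Visit cleaning, meal aggregation, daily components and circadian strength."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feedwatch.components import (
    aggregate_meals,
    circadian_strength,
    clean_visits,
    compute_daily_components,
    daily_components,
    hourly_intake,
    night_intake,
    wavelet_preprocess,
)
from feedwatch.config import CleaningRules


def _visits(rows):
    df = pd.DataFrame(
        rows, columns=["pig_id", "start", "duration_s", "intake_kg"]
    )
    df["start"] = pd.to_datetime(df["start"])
    df["pen_id"] = "P1"
    df["round_id"] = 1
    return df


class TestCleanVisits:
    def test_all_valid_input_unchanged(self):
        v = _visits([("a", "2022-01-03 08:00", 100.0, 0.2)])
        out, log = clean_visits(v)
        assert len(out) == 1 and out["intake_kg"].notna().all()
        assert sum(log.values()) == 0

    def test_negative_intake_fully_removed(self):
        v = _visits(
            [("a", "2022-01-03 08:00", 100.0, -0.2), ("a", "2022-01-03 09:00", 100.0, 0.2)]
        )
        out, log = clean_visits(v)
        assert len(out) == 1 and log["negative"] == 1

    def test_zero_duration_with_intake_removed(self):
        v = _visits([("a", "2022-01-03 08:00", 0.0, 0.2)])
        out, log = clean_visits(v)
        assert len(out) == 0 and log["zero_duration_with_intake"] == 1

    def test_rate_ceiling_nulls_values_keeps_timing(self):
        v = _visits([("a", "2022-01-03 08:00", 10.0, 0.9)])  # 90 g/s
        out, log = clean_visits(v, CleaningRules(rate_ceiling_g_s=5.0))
        assert len(out) == 1
        assert out["intake_kg"].isna().all() and out["duration_s"].isna().all()
        assert out["start"].iloc[0] == pd.Timestamp("2022-01-03 08:00")
        assert log["rate_ceiling_nulled"] == 1


class TestAggregateMeals:
    def test_gap_below_criterion_merges(self):
        v = _visits(
            [("a", "2022-01-03 08:00:00", 100.0, 0.2), ("a", "2022-01-03 08:02:00", 50.0, 0.1)]
        )  # gap = 120 - 100 = 20 s
        meals = aggregate_meals(v, 43.0)
        assert len(meals) == 1
        assert meals["intake_kg"].iloc[0] == pytest.approx(0.3)
        assert meals["duration_s"].iloc[0] == pytest.approx(150.0)
        assert meals["n_visits"].iloc[0] == 2

    def test_gap_at_or_above_criterion_splits(self):
        v = _visits(
            [("a", "2022-01-03 08:00:00", 60.0, 0.2), ("a", "2022-01-03 08:02:00", 50.0, 0.1)]
        )  # gap = 60 s
        assert len(aggregate_meals(v, 43.0)) == 2

    def test_transitive_merge_chain(self):
        """Five visits with 29-s gaps under criterion 30 collapse to one
        meal; brute-force over the gap list gives the same grouping."""
        rows, t = [], pd.Timestamp("2022-01-03 08:00:00")
        for _ in range(5):
            rows.append(("a", t, 60.0, 0.1))
            t = t + pd.Timedelta(seconds=60 + 29)
        meals = aggregate_meals(_visits(rows), 30.0)
        gaps = [29.0] * 4
        n_expected = 1 + sum(g >= 30.0 for g in gaps)
        assert len(meals) == n_expected == 1
        assert meals["n_visits"].iloc[0] == 5

    @given(
        gaps=st.lists(st.floats(0.0, 120.0, allow_nan=False), min_size=0, max_size=12),
        criterion=st.floats(1.0, 90.0, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_meal_count_matches_gap_oracle(self, gaps, criterion):
        """Number of meals equals 1 + number of inter-visit gaps at or above
        the criterion, for any gap sequence."""
        rows, t = [], pd.Timestamp("2022-01-03 08:00:00")
        dur = 30.0
        rows.append(("a", t, dur, 0.1))
        for g in gaps:
            t = t + pd.Timedelta(seconds=dur + g)
            rows.append(("a", t, dur, 0.1))
        meals = aggregate_meals(_visits(rows), criterion)
        # timestamp arithmetic is ns-exact, so the oracle comparison is too
        expected = 1 + sum(
            pd.Timedelta(seconds=g).value / 1e9 >= criterion for g in gaps
        )
        assert len(meals) == expected
        assert meals["n_visits"].sum() == len(rows)

    def test_idempotent_reaggregation(self):
        v = _visits(
            [
                ("a", "2022-01-03 08:00:00", 100.0, 0.2),
                ("a", "2022-01-03 08:02:00", 50.0, 0.1),
                ("a", "2022-01-03 09:00:00", 50.0, 0.1),
            ]
        )
        meals = aggregate_meals(v, 43.0)
        again = aggregate_meals(meals.drop(columns=["n_visits", "date"]), 43.0)
        assert len(again) == len(meals)
        pd.testing.assert_series_equal(
            again["intake_kg"], meals["intake_kg"], check_index=False
        )


class TestDailyComponents:
    def test_arithmetic(self):
        meals = pd.DataFrame(
            {
                "pig_id": ["a", "a"],
                "pen_id": "P1",
                "round_id": 1,
                "date": pd.to_datetime(["2022-01-03", "2022-01-03"]),
                "start": pd.to_datetime(["2022-01-03 08:00", "2022-01-03 12:00"]),
                "duration_s": [100.0, 200.0],
                "intake_kg": [0.2, 0.3],
            }
        )
        d = daily_components(meals)
        assert d["intake"].iloc[0] == pytest.approx(0.5)
        assert d["duration"].iloc[0] == pytest.approx(300.0)
        assert d["frequency"].iloc[0] == 2
        assert d["rate"].iloc[0] == pytest.approx(500.0 / 300.0)

    def test_covered_day_without_meals_is_true_zero(self):
        meals = pd.DataFrame(
            {
                "pig_id": ["a"],
                "pen_id": "P1",
                "round_id": 1,
                "date": pd.to_datetime(["2022-01-03"]),
                "start": pd.to_datetime(["2022-01-03 08:00"]),
                "duration_s": [100.0],
                "intake_kg": [0.2],
            }
        )
        coverage = pd.DataFrame(
            {"pig_id": "a", "date": pd.to_datetime(["2022-01-03", "2022-01-04"])}
        )
        d = daily_components(meals, coverage).set_index("date")
        day2 = d.loc[pd.Timestamp("2022-01-04")]
        assert day2["intake"] == 0.0 and day2["frequency"] == 0
        assert np.isnan(day2["rate"])  # rate undefined at zero duration


class TestNightIntake:
    @pytest.mark.parametrize(
        "hour_intakes, expected",
        [
            ({22: 1.0}, 1.0),
            ({12: 1.0}, 0.0),
            ({2: 0.25, 10: 0.75}, 0.25),
        ],
    )
    def test_proportions(self, hour_intakes, expected):
        rows = [
            {"pig_id": "a", "date": pd.Timestamp("2022-01-03"), "hour": h,
             "intake_kg": hour_intakes.get(h, 0.0)}
            for h in range(24)
        ]
        out = night_intake(pd.DataFrame(rows))
        assert out["night_intake"].iloc[0] == pytest.approx(expected)

    def test_zero_intake_day_is_missing(self):
        rows = [
            {"pig_id": "a", "date": pd.Timestamp("2022-01-03"), "hour": h, "intake_kg": 0.0}
            for h in range(24)
        ]
        out = night_intake(pd.DataFrame(rows))
        assert np.isnan(out["night_intake"].iloc[0])


def test_intake_conservation_through_pipeline(small_cfg):
    from feedwatch.synthetic import generate_visits

    visits = generate_visits(small_cfg)
    daily, meals, _ = compute_daily_components(visits, 43.0)
    assert daily["intake"].sum() == pytest.approx(visits["intake_kg"].sum(), rel=1e-9)
    assert daily["night_intake"].dropna().between(0, 1).all()
    # frequency equals the number of meals exactly
    per_day = meals.groupby(["pig_id", "date"]).size()
    joined = daily.set_index(["pig_id", "date"])["frequency"]
    for key, n in per_day.items():
        assert joined[key] == n


class TestWaveletPreprocess:
    def test_constant_series_becomes_zero(self):
        x, missing = wavelet_preprocess(np.full(24 * 10, 3.0))
        assert np.allclose(x, 0.0) and not missing.any()

    def test_nan_hours_zeroed_and_flagged(self):
        raw = np.ones(24 * 10)
        raw[30:35] = np.nan
        x, missing = wavelet_preprocess(raw)
        assert missing[30:35].all() and missing.sum() == 5
        assert np.all(x[30:35] == 0.0)

    def test_sinusoid_period_preserved(self):
        t = np.arange(24 * 14)
        raw = 2.0 + np.sin(2 * np.pi * t / 24)
        x, _ = wavelet_preprocess(raw)
        # dominant FFT frequency unchanged at 1/24 per hour
        for sig in (raw - raw.mean(), x):
            f = np.fft.rfftfreq(len(sig))
            peak = f[np.argmax(np.abs(np.fft.rfft(sig)))]
            assert peak == pytest.approx(1 / 24, abs=1e-3)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            wavelet_preprocess(np.ones(100), window_h=168)


class TestCircadianStrength:
    def test_sinusoid_stronger_than_noise(self):
        t = np.arange(24 * 12)
        sin = np.sin(2 * np.pi * t / 24)
        rng = np.random.default_rng(0)
        noise = rng.normal(0, np.std(sin), len(t))
        s_sin = circadian_strength(sin)
        s_noise = circadian_strength(noise)
        mid = slice(3, 9)  # avoid transform edges
        assert np.nanmedian(s_sin[mid]) > np.nanmedian(s_noise[mid])

    def test_all_zero_series_zero_strength(self):
        s = circadian_strength(np.zeros(24 * 8))
        assert np.allclose(s[np.isfinite(s)], 0.0)

    def test_missing_day_masks_two_days_each_side(self):
        t = np.arange(24 * 15)
        s = circadian_strength(np.sin(2 * np.pi * t / 24),
                               missing_days=np.arange(15) == 9)  # day 10 (1-based)
        missing_days = np.flatnonzero(~np.isfinite(s)) + 1
        assert list(missing_days) == [8, 9, 10, 11, 12]

    def test_phase_shift_invariance(self):
        """Shifting a 24-h sinusoid by whole hours leaves the daily median
        in-band power unchanged on interior days."""
        t = np.arange(24 * 20)
        a = circadian_strength(np.sin(2 * np.pi * t / 24))
        b = circadian_strength(np.sin(2 * np.pi * (t - 5) / 24))
        mid = slice(6, 14)
        scale = np.nanmax(a)
        assert np.nanmax(np.abs(a[mid] - b[mid])) < 1e-6 * scale

    def test_all_missing_returns_all_missing(self):
        s = circadian_strength(np.zeros(24 * 6), missing_days=np.ones(6, bool))
        assert np.isnan(s).all()

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            circadian_strength(np.zeros(24 * 4))
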