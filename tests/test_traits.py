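from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fattenassoc.synthetic_herd import generate_herd
from fattenassoc.traits import (
    DegenerateIntervalError,
    FeedSeries,
    TargetBeforeStartError,
    TargetNotReachedError,
    TargetScheme,
    WeighSeries,
    covariate_columns_for,
    days_to_reach,
    derive_traits,
    interval_traits,
    season_at,
    total_traits,
)


def _series(days, weights, aid="a1"):
    return WeighSeries(aid, np.array(days, float), np.array(weights, float))


class TestDaysToReach:
    def test_linear_interpolation(self):
        assert days_to_reach(_series([100, 130], [95, 110]), 100) == pytest.approx(110.0)

    def test_exact_hit_returns_record_day(self):
        assert days_to_reach(_series([0, 90, 120], [80, 100, 120]), 100) == 90.0

    def test_not_reached_raises(self):
        with pytest.raises(TargetNotReachedError):
            days_to_reach(_series([0, 30], [80, 95]), 100)

    def test_target_below_start_raises(self):
        with pytest.raises(TargetBeforeStartError):
            days_to_reach(_series([0, 30], [120, 150]), 100)

    def test_first_upward_crossing_on_local_decrease(self):
        # dips below the target after first crossing it; first crossing counts
        s = _series([0, 30, 60, 90], [90, 105, 99, 130])
        assert days_to_reach(s, 100) == pytest.approx(30 * 10 / 15)

    @given(st.lists(st.floats(0.1, 3.0), min_size=3, max_size=12))
    def test_monotone_in_target(self, gains):
        weights = 80 + np.cumsum([0] + gains)
        s = _series(np.arange(len(weights)) * 30.0, weights)
        targets = np.linspace(weights[0], weights[-1], 5)
        dtrs = [days_to_reach(s, t) for t in targets]
        assert all(b >= a for a, b in zip(dtrs, dtrs[1:]))


class TestIntervalTraits:
    def test_constant_rates(self):
        # 2 kg/day gain from 100 kg, 6 kg/day intake, targets 50 days apart
        days = np.arange(0, 101, 10.0)
        s = _series(days, 100 + 2 * days)
        feed = FeedSeries("a1", np.arange(100), np.full(100, 6.0))
        scheme = TargetScheme((100.0, 200.0, 300.0))
        fp, dmi, ddmi, fcr, adwg = interval_traits(s, feed, scheme, 0, 1)
        assert (fp, dmi, ddmi, adwg, fcr) == pytest.approx((50.0, 300.0, 6.0, 2.0, 3.0))

    def test_fractional_day_prorating(self):
        # crossing at day 2.5: half of day 2's intake belongs to the interval
        s = _series([0.0, 5.0], [100.0, 120.0])
        feed = FeedSeries("a1", np.arange(5), np.array([1.0, 2.0, 4.0, 8.0, 16.0]))
        scheme = TargetScheme((110.0, 120.0))
        fp, dmi, _, _, _ = interval_traits(s, feed, scheme, 0, 1)
        assert fp == pytest.approx(2.5)
        assert dmi == pytest.approx(0.5 * 4.0 + 8.0 + 16.0)

    def test_total_traits_constant_rate(self):
        days = np.arange(0, 201, 10.0)
        s = _series(days, 100 + 2 * days)
        feed = FeedSeries("a1", np.arange(200), np.full(200, 6.0))
        fw, span, tdmi, tddmi, tfcr, tadwg = total_traits(s, feed, TargetScheme((100.0, 400.0)))
        assert fw == pytest.approx(500.0)
        assert tfcr == pytest.approx(3.0)
        assert tfcr * tadwg == pytest.approx(tddmi, abs=1e-9)

    def test_degenerate_interval(self):
        s = _series([0.0, 10.0], [100.0, 200.0])
        feed = FeedSeries("a1", np.arange(10), np.full(10, 5.0))
        with pytest.raises(DegenerateIntervalError):
            interval_traits(s, feed, TargetScheme((150.0, 160.0)), 0, 0)


class TestSeasonAt:
    @pytest.mark.parametrize(
        "start, day, season",
        [
            (date(2016, 1, 1), 0, "winter"),
            (date(2016, 1, 1), 182, "summer"),
            (date(2016, 3, 1), 0, "spring"),
            (date(2016, 11, 30), 1, "winter"),
        ],
    )
    def test_meteorological_quarters(self, start, day, season):
        assert season_at(start, day) == season

    def test_total_over_a_year(self):
        labels = {season_at(date(2016, 1, 1), d) for d in range(366)}
        assert labels == {"winter", "spring", "summer", "autumn"}


class TestDeriveTraits:
    def test_closed_forms_on_noise_free_animal(self, noise_free_config):
        herd = generate_herd(noise_free_config)
        table = derive_traits(herd.weights, herd.feed, herd.animals, TargetScheme())
        row = table.iloc[0]
        # weight is exactly 80 + t, so DTR(w) = w - 80
        for target, label in zip((100, 200, 300, 400, 450), ("W1", "W2", "W3", "W4", "W5")):
            assert row[f"DTR{label}"] == pytest.approx(target - 80, abs=1e-9)
        assert row["W1-W2 FP"] == pytest.approx(100.0)
        assert row["W1-W2 ADWG"] == pytest.approx(1.0)
        # interval DMI equals the discrete sum of the closed-form intake
        expected = sum(0.1 * (80 + t) ** 0.75 for t in range(20, 120))
        assert row["W1-W2 DMI"] == pytest.approx(expected, abs=1e-9)
        assert row["W1-W2 FCR"] == pytest.approx(expected / 100.0, abs=1e-12)

    def test_fcr_adwg_ddmi_identity(self, small_herd):
        table = derive_traits(small_herd.weights, small_herd.feed, small_herd.animals)
        for iv in ("W1-W2", "W2-W3", "W3-W4", "W4-W5"):
            lhs = table[f"{iv} FCR"] * table[f"{iv} ADWG"]
            diff = (lhs - table[f"{iv} DDMI"]).abs().dropna()
            assert (diff < 1e-9).all()
        diff = (table["TFCR"] * table["TADWG"] - table["TDDMI"]).abs().dropna()
        assert (diff < 1e-9).all()

    def test_unreached_target_yields_nan_not_extrapolation(self):
        animals = pd.DataFrame(
            {"animal_id": ["a1"], "start_date": ["2016-01-01"], "age_at_start_days": [100]}
        )
        weights = pd.DataFrame(
            {"animal_id": ["a1"] * 3, "day": [0, 30, 60], "weight_kg": [90.0, 150.0, 210.0]}
        )
        feed = pd.DataFrame(
            {"animal_id": ["a1"] * 60, "day": range(60), "dmi_kg": [5.0] * 60}
        )
        table = derive_traits(weights, feed, animals, TargetScheme((100.0, 200.0, 450.0)))
        row = table.iloc[0]
        assert np.isfinite(row["DTRW1"]) and np.isfinite(row["DTRW2"])
        assert np.isnan(row["DTRW3"])
        assert np.isnan(row["W2-W3 FP"])


def test_covariate_anchoring():
    assert covariate_columns_for("DTRW3") == ("age_at_W3", "season_at_W3")
    assert covariate_columns_for("W2-W3 FCR") == ("age_at_W3", "season_at_W3")
    assert covariate_columns_for("TADWG") == ("age_at_final", "season_at_final")
    assert covariate_columns_for("FW") == ("age_at_final", "season_at_final")
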