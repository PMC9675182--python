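"""Delta-change projection, bilinear interpolation and scenario comparison."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from dtrheat import (
    AnomalyField,
    DistrictMeta,
    ThresholdConfig,
    apply_anomaly,
    bilinear_interpolate,
    compare_scenarios,
    derive_daily,
    detect_events,
    pct_change,
    qualify_days,
    read_anomaly_csv,
)
from dtrheat import synthetic

META = DistrictMeta("D1", "TestProv", mmt=20.0, centroid_lat=-29.0,
                    centroid_lon=25.0, coastal=False)


def grid_field(values, lats=(0.0, 1.0), lons=(0.0, 1.0), variable="tmax"):
    return AnomalyField.gridded("RCPX", variable, lats, lons, np.asarray(values, float))


class TestBilinearInterpolate:
    def test_node_identity(self):
        f = grid_field([[0.0, 1.0], [2.0, 3.0]])
        for (lat, lon), expected in {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 2.0, (1, 1): 3.0}.items():
            assert bilinear_interpolate(f, lat, lon)[0] == pytest.approx(expected)

    def test_cell_centre_is_corner_average(self):
        f = grid_field([[1.0, 2.0], [5.0, 10.0]])
        assert bilinear_interpolate(f, 0.5, 0.5)[0] == pytest.approx(4.5)

    def test_interior_point_matches_closed_form(self):
        # corners f(0,0)=0 f(0,1)=1 f(1,0)=2 f(1,1)=3 at (lat,lon)=(0.25,0.75):
        # (1-.25)(1-.75)*0 + (1-.25)(.75)*1 + (.25)(1-.75)*2 + (.25)(.75)*3 = 1.25
        f = grid_field([[0.0, 1.0], [2.0, 3.0]])
        assert bilinear_interpolate(f, 0.25, 0.75)[0] == pytest.approx(1.25)

    def test_linear_in_field_values(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 3, 4))
        lats, lons = np.arange(3.0), np.arange(4.0)
        fa = AnomalyField.gridded("S", "tmax", lats, lons, a)
        fb = AnomalyField.gridded("S", "tmax", lats, lons, b)
        fab = AnomalyField.gridded("S", "tmax", lats, lons, 2.0 * a + 3.0 * b)
        p = (1.3, 2.1)
        assert bilinear_interpolate(fab, *p)[0] == pytest.approx(
            2.0 * bilinear_interpolate(fa, *p)[0] + 3.0 * bilinear_interpolate(fb, *p)[0]
        )

    def test_outside_bounding_box_is_error(self):
        f = grid_field([[0.0, 1.0], [2.0, 3.0]])
        with pytest.raises(ValueError, match="outside"):
            bilinear_interpolate(f, 2.0, 0.5)


def observed_series(seed=0, noise=2.0):
    regime = synthetic.DistrictRegime(
        district_id="D1", coastal=False, tmax_mean_annual=27.0,
        seasonal_amplitude_tmax=5.5, seasonal_amplitude_tmin=7.0,
        dtr_base=13.0, noise_sd=noise, mmt=20.0,
    )
    return synthetic.generate_series(regime, seed=seed)


def fields_for(d_tmax, d_tmin, scenario="S"):
    return list(synthetic.generate_anomaly(scenario, d_tmax, d_tmin, district_ids=["D1"]))


class TestApplyAnomaly:
    def test_zero_anomaly_identity_on_base_period(self):
        s = observed_series()
        fut = apply_anomaly(s, fields_for(0.0, 0.0), META, ("2014-01-01", "2019-12-31"))
        pd.testing.assert_frame_equal(fut.frame, s.frame)
        # events identical downstream, event for event
        cfg = ThresholdConfig()
        assert detect_events(derive_daily(fut), META, cfg) == \
            detect_events(derive_daily(s), META, cfg)

    def test_tmax_only_delta_raises_dtr_by_delta(self):
        s = observed_series()
        fut = apply_anomaly(s, fields_for(2.0, 0.0), META, ("2014-01-01", "2019-12-31"))
        d0, d1 = derive_daily(s), derive_daily(fut)
        np.testing.assert_allclose(d1["dtr"].dropna(), d0["dtr"].dropna() + 2.0)

    def test_uniform_shift_preserves_dtr_moves_tmean(self):
        s = observed_series()
        fut = apply_anomaly(s, fields_for(1.5, 1.5), META, ("2014-01-01", "2019-12-31"))
        d0, d1 = derive_daily(s), derive_daily(fut)
        np.testing.assert_allclose(d1["dtr"].dropna(), d0["dtr"].dropna())
        np.testing.assert_allclose(d1["tmean"].dropna(), d0["tmean"].dropna() + 1.5)

    def test_tmax_delta_never_decreases_qualifying_days(self):
        s = observed_series()
        d0 = derive_daily(s)
        fut = apply_anomaly(s, fields_for(2.0, 0.0), META, ("2014-01-01", "2019-12-31"))
        d1 = derive_daily(fut)
        assert qualify_days(d1, META.mmt).sum() >= qualify_days(d0, META.mmt).sum()

    def test_missing_days_stay_missing(self):
        s, _ = synthetic.inject_missingness(observed_series(), 0.2, seed=5)
        fut = apply_anomaly(s, fields_for(2.0, 1.0), META, ("2014-01-01", "2019-12-31"))
        pd.testing.assert_series_equal(fut.missing_mask, s.missing_mask)

    def test_calendar_cycling_covers_future_period(self):
        s = observed_series()
        fut = apply_anomaly(s, fields_for(0.0, 0.0), META, ("2020-01-01", "2039-12-31"))
        assert fut.period_start == dt.date(2020, 1, 1)
        assert fut.period_end == dt.date(2039, 12, 31)
        # 2020 maps from 2014 month/day-aligned
        assert fut.frame.at[pd.Timestamp("2020-03-05"), "tmax"] == \
            s.frame.at[pd.Timestamp("2014-03-05"), "tmax"]
        # Feb 29 2020: source year 2014 lacks it -> maps from Feb 28
        assert fut.frame.at[pd.Timestamp("2020-02-29"), "tmax"] == \
            s.frame.at[pd.Timestamp("2014-02-28"), "tmax"]

    def test_inverted_projected_day_set_missing_with_warning(self):
        s = observed_series(noise=0.0)
        # a tmin-only delta larger than the smallest DTR inverts some days
        big = float((s.frame["tmax"] - s.frame["tmin"]).min()) + 1.0
        with pytest.warns(UserWarning, match="tmax < tmin"):
            fut = apply_anomaly(s, fields_for(0.0, big), META,
                                ("2014-01-01", "2019-12-31"))
        assert fut.missing_mask.any()

    def test_partial_year_base_period_is_error(self):
        s = observed_series()
        trimmed = type(s)("D1", s.frame.iloc[10:])
        with pytest.raises(ValueError, match="whole calendar years"):
            apply_anomaly(trimmed, fields_for(0.0, 0.0), META,
                          ("2020-01-01", "2020-12-31"))

    def test_gridded_field_interpolated_at_centroid(self):
        s = observed_series()
        lats, lons = np.array([-30.0, -28.0]), np.array([24.0, 26.0])
        values = np.full((12, 2, 2), 2.0)
        f_tmax = AnomalyField.gridded("S", "tmax", lats, lons, values,
                                      time_index=range(1, 13))
        fut = apply_anomaly(s, f_tmax, META, ("2014-01-01", "2019-12-31"))
        np.testing.assert_allclose(fut.frame["tmax"], s.frame["tmax"] + 2.0)


class TestPctChange:
    def test_printed_summer_increases(self):
        # 150 observed vs 270 under the moderate scenario, 281 under the high one
        assert pct_change(150, 270).rounded == 80
        assert pct_change(150, 270).raw == pytest.approx(80.0)
        assert pct_change(150, 281).rounded == 87
        assert pct_change(150, 281).raw == pytest.approx(87.3333333)

    def test_no_change_is_zero(self):
        assert pct_change(42, 42).rounded == 0

    def test_zero_observed_is_undefined_not_infinite(self):
        pc = pct_change(0, 10)
        assert not pc.defined
        assert pc.rounded is None
        assert np.isnan(pc.raw)


class TestCompareScenarios:
    def _events(self, masks):
        events = []
        for district, mask in masks.items():
            meta = DistrictMeta(district, "P", 20.0, -29.0, 25.0, False)
            from test_detection import detect_on_mask
            events.extend(detect_on_mask(mask, meta))
        return events

    def test_identical_sets_all_zero_change(self):
        ev = self._events({"D1": [1, 1, 0, 1, 1, 1]})
        table = compare_scenarios(ev, ev, "district", scenario="S")
        assert (table["pct_change_events"] == 0).all()
        assert (table["pct_change_event_days"] == 0).all()

    def test_one_extra_summer_event(self):
        obs = self._events({"D1": [1, 1, 0, 0, 0, 0]})
        fut = self._events({"D1": [1, 1, 0, 1, 1, 0]})
        table = compare_scenarios(obs, fut, "season", scenario="S").set_index("season")
        assert table.at["summer", "observed_events"] == 1
        assert table.at["summer", "future_events"] == 2
        assert table.at["summer", "pct_change_events"] == 100
        for season in ("autumn", "winter", "spring"):
            assert table.at[season, "future_events"] == 0

    def test_planted_counts_match_hand_tally(self):
        obs = self._events({"A": [1, 1, 0, 1, 1], "B": [1, 1, 1]})
        fut = self._events({"A": [1, 1, 1, 1, 1], "B": [1, 1, 1]})
        table = compare_scenarios(obs, fut, "district", scenario="S").set_index("district")
        assert table.at["A", "observed_events"] == 2
        assert table.at["A", "future_events"] == 1
        assert table.at["A", "observed_event_days"] == 4
        assert table.at["A", "future_event_days"] == 5
        assert table.at["B", "pct_change_events"] == 0


class TestAnomalyCsv:
    def test_round_trip_per_district(self, tmp_path):
        rows = ["scenario,variable,time,district,delta"]
        for m in range(1, 13):
            rows += [f"RCP4.5,tmax,{m},D1,1.5", f"RCP4.5,tmin,{m},D1,1.0"]
        p = tmp_path / "anoms.csv"
        p.write_text("\n".join(rows) + "\n")
        fields = read_anomaly_csv(p)
        assert {f.variable for f in fields} == {"tmax", "tmin"}
        f_tmax = next(f for f in fields if f.variable == "tmax")
        assert f_tmax.time_resolution == "monthly"
        assert f_tmax.deltas_for_district(META).tolist() == [1.5] * 12

    def test_gridded_csv(self, tmp_path):
        rows = ["scenario,variable,time,lat,lon,delta"]
        for m in range(1, 13):
            for lat in (-30.0, -28.0):
                for lon in (24.0, 26.0):
                    rows.append(f"RCP8.5,tmax,{m},{lat},{lon},2.0")
        p = tmp_path / "anoms_grid.csv"
        p.write_text("\n".join(rows) + "\n")
        (field,) = read_anomaly_csv(p)
        assert field.is_gridded
        assert bilinear_interpolate(field, -29.0, 25.0) == pytest.approx([2.0] * 12)
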