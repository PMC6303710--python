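"""Wet-thermal accumulation: closed forms, monotonicity, spring cutoff."""

import math
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from wetgerm import predictor
from wetgerm.field_io import FieldSeries
from wetgerm.synthetic_data import FieldSimConfig, simulate_field_series
from wetgerm.thermal_model import RateCurve, WetThermalModel

#: rate(15 °C) = 0.2/day → 5 days to completion when always wet.
CURVE = RateCurve("A", 50.0, a=0.0, b=0.0, c=0.2, tmin=5, tmax=25)
#: temperature-sensitive curve: positive between ~3 °C and ~35 °C, peaking
#: near 19 °C; used by the seasonal-scan tests.
TCURVE = RateCurve("A", 50.0, a=-0.0008, b=0.0306, c=-0.083, tmin=5, tmax=25)


def constant_series(start="2015-10-01", days=40, temp=15.0, psi=-0.3):
    cfg = FieldSimConfig(
        start=datetime.fromisoformat(start),
        end=datetime.fromisoformat(start) + timedelta(days=days),
        temp_trend=temp, diurnal_amplitude=0.0, noise_sd=0.0,
        wet_psi=psi if psi > -3.0 else -0.1, dry_psi=-3.0,
    )
    s = simulate_field_series(cfg)
    if psi <= -3.0:
        s.frame["water_potential_mpa"] = psi
    return s


def make_model(curve=CURVE, psi_b=-1.5):
    return WetThermalModel(curves={(curve.treatment, curve.percentile): curve},
                           psi_b=psi_b)


class TestAccumulate:
    def test_constant_conditions_closed_form(self):
        s = constant_series()
        trace = predictor.accumulate(CURVE, s, "2015-10-03")
        assert trace.completed
        expected = pd.Timestamp("2015-10-03") + pd.Timedelta(days=5)
        assert abs(trace.completion_time - expected) <= pd.Timedelta(hours=1)

    def test_dry_block_delays_by_its_duration(self):
        wet = constant_series()
        dry = constant_series()
        planting = pd.Timestamp("2015-10-03")
        mask = (dry.frame["timestamp"] >= planting + pd.Timedelta(days=2)) & (
            dry.frame["timestamp"] < planting + pd.Timedelta(days=4)
        )
        dry.frame.loc[mask, "water_potential_mpa"] = -2.0
        t_wet = predictor.accumulate(CURVE, wet, planting).completion_time
        t_dry = predictor.accumulate(CURVE, dry, planting).completion_time
        assert t_dry - t_wet == pd.Timedelta(days=2)

    def test_never_wet_no_progress(self):
        s = constant_series(psi=-3.0)
        trace = predictor.accumulate(CURVE, s, "2015-10-03", psi_b=-1.5)
        assert not trace.completed
        assert trace.progress[-1] == 0.0
        assert trace.wet_time == pd.Timedelta(0)

    def test_boundary_wetness_inclusive_by_default(self):
        s = constant_series()
        s.frame["water_potential_mpa"] = -1.5
        inclusive = predictor.accumulate(CURVE, s, "2015-10-03", psi_b=-1.5)
        strict = predictor.accumulate(
            CURVE, s, "2015-10-03", psi_b=-1.5, wet_inclusive=False
        )
        assert inclusive.completed
        assert not strict.completed

    def test_planting_after_series_end_rejected(self):
        s = constant_series(days=10)
        with pytest.raises(ValueError, match="after the series end"):
            predictor.accumulate(CURVE, s, "2016-01-01")

    def test_progress_nondecreasing_and_sums_increments(self):
        cfg = FieldSimConfig(
            start=datetime(2015, 10, 1), end=datetime(2015, 11, 15),
            temp_trend=8.0, diurnal_amplitude=10.0, noise_sd=1.0,
            wet_windows=[(datetime(2015, 10, 5), datetime(2015, 10, 20)),
                         (datetime(2015, 11, 1), datetime(2015, 11, 15))],
            rng_seed=5,
        )
        s = simulate_field_series(cfg)
        trace = predictor.accumulate(CURVE, s, "2015-10-01")
        assert (np.diff(trace.progress) >= -1e-12).all()

    def test_split_record_changes_completion_by_less_than_one_step(self):
        s = constant_series()
        planting = "2015-10-03"
        base = predictor.accumulate(CURVE, s, planting).completion_time
        # insert a record mid-interval, two days in
        frame = s.frame
        mid = pd.Timestamp("2015-10-05 00:30:00")
        extra = pd.DataFrame({
            "timestamp": [mid], "soil_temp_c": [15.0],
            "water_potential_mpa": [-0.3],
        })
        split = FieldSeries(
            site_year="s",
            frame=pd.concat([frame, extra]).sort_values("timestamp").reset_index(drop=True),
        )
        after = predictor.accumulate(CURVE, split, planting).completion_time
        assert abs(after - base) <= pd.Timedelta(hours=1)

    def test_missing_sensor_values_contribute_nothing(self):
        s = constant_series()
        planting = pd.Timestamp("2015-10-03")
        mask = (s.frame["timestamp"] >= planting + pd.Timedelta(days=1)) & (
            s.frame["timestamp"] < planting + pd.Timedelta(days=2)
        )
        s.frame.loc[mask, "soil_temp_c"] = np.nan
        trace = predictor.accumulate(CURVE, s, planting, max_gap=pd.Timedelta(days=99))
        # one day of missing data = one day of delay
        expected = planting + pd.Timedelta(days=6)
        assert abs(trace.completion_time - expected) <= pd.Timedelta(hours=1)


class TestPredictionTable:
    def test_row_per_treatment_and_percentile(self):
        curves = {}
        for tr in ("A", "B"):
            for pct, c in [(10.0, 0.5), (50.0, 0.2), (90.0, 0.1)]:
                curves[(tr, pct)] = RateCurve(tr, pct, 0.0, 0.0, c)
        model = WetThermalModel(curves=curves)
        s = constant_series()
        table = predictor.predict_dates_for_planting(model, s, "2015-10-03")
        assert len(table.frame) == 6
        assert table.frame["predicted_date"].notna().all()

    def test_higher_percentile_never_earlier(self):
        # rates non-increasing in percentile at every temperature
        curves = {
            ("A", pct): RateCurve("A", pct, 0.0, 0.0, c)
            for pct, c in [(10.0, 0.5), (50.0, 0.2), (90.0, 0.1)]
        }
        model = WetThermalModel(curves=curves)
        s = constant_series(days=60)
        table = predictor.predict_dates_for_planting(model, s, "2015-10-03")
        dates = table.frame.sort_values("percentile")["predicted_date"]
        assert dates.is_monotonic_increasing

    def test_entirely_dry_series_all_not_reached(self):
        s = constant_series(psi=-3.0)
        table = predictor.predict_dates_for_planting(make_model(), s, "2015-10-03")
        assert table.frame["predicted_date"].isna().all()


def cooling_series(seed=11):
    """Warm autumn cooling into winter, warming again in spring; always wet."""
    cfg = FieldSimConfig(
        start=datetime(2015, 9, 1), end=datetime(2016, 5, 31),
        temp_trend=[
            (datetime(2015, 9, 1), 22.0),
            (datetime(2016, 1, 15), 0.5),
            (datetime(2016, 5, 31), 18.0),
        ],
        diurnal_amplitude=6.0, noise_sd=0.3, rng_seed=seed,
    )
    return simulate_field_series(cfg)


class TestPlantingScan:
    def test_constant_conditions_every_date_closed_form(self):
        s = constant_series(days=60)
        scan = predictor.predict_planting_scan(
            make_model(), s, 50.0, "2015-10-01", "2015-10-30"
        )
        assert len(scan.frame) == 30
        for rec in scan.frame.itertuples(index=False):
            expected = rec.planting_date + pd.Timedelta(days=5)
            assert abs(rec.predicted_date - expected) <= pd.Timedelta(hours=1)

    def test_scan_matches_independent_accumulation(self):
        s = cooling_series()
        scan = predictor.predict_planting_scan(
            make_model(TCURVE), s, 50.0, "2015-09-01", "2015-12-01"
        )
        for rec in scan.frame.iloc[::13].itertuples(index=False):
            trace = predictor.accumulate(TCURVE, s, rec.planting_date, psi_b=-1.5)
            if pd.isna(rec.predicted_date):
                assert trace.completion_time is None
            else:
                assert trace.completion_time == rec.predicted_date

    def test_monotone_in_planting_date(self):
        s = cooling_series()
        scan = predictor.predict_planting_scan(
            make_model(TCURVE), s, 50.0, "2015-09-01", "2016-02-28"
        )
        dates = scan.frame["predicted_date"]
        filled = dates.fillna(pd.Timestamp.max)
        assert filled.is_monotonic_increasing

    def test_planting_after_last_wetting_not_reached(self):
        cfg = FieldSimConfig(
            start=datetime(2015, 9, 1), end=datetime(2015, 12, 1),
            temp_trend=15.0, diurnal_amplitude=0.0, noise_sd=0.0,
            wet_windows=[(datetime(2015, 9, 1), datetime(2015, 10, 1))],
        )
        s = simulate_field_series(cfg)
        scan = predictor.predict_planting_scan(
            make_model(), s, 50.0, "2015-10-02", "2015-10-10"
        )
        assert scan.frame["predicted_date"].isna().all()

    def test_scan_outside_series_rejected(self):
        s = constant_series(days=20)
        with pytest.raises(ValueError, match="outside"):
            predictor.predict_planting_scan(
                make_model(), s, 50.0, "2015-09-01", "2015-10-10"
            )


class TestSpringPlantingDate:
    def test_threshold_crossing_found(self):
        s = cooling_series()
        scan = predictor.predict_planting_scan(
            make_model(TCURVE), s, 50.0, "2015-09-01", "2016-02-28"
        )
        result = predictor.spring_planting_date(scan, cutoff="2016-03-01")
        assert len(result) == 1
        rec = result.iloc[0]
        assert rec["status"] == predictor.STATUS_GERMINATES_AFTER_CUTOFF
        crossing = rec["planting_date"]
        # verify it is the unique crossing: all earlier plantings germinate
        # before the cutoff, the crossing and everything after on/after it
        frame = scan.frame.set_index("planting_date")
        before = frame.loc[: crossing - pd.Timedelta(days=1), "predicted_date"]
        at_after = frame.loc[crossing:, "predicted_date"]
        assert (before < pd.Timestamp("2016-03-01")).all()
        assert (at_after >= pd.Timestamp("2016-03-01")).all()

    def test_all_dates_qualify_returns_scan_start(self):
        # so cold all winter that nothing germinates before the cutoff
        cfg = FieldSimConfig(
            start=datetime(2015, 11, 1), end=datetime(2016, 4, 30),
            temp_trend=[
                (datetime(2015, 11, 1), 1.0),
                (datetime(2016, 3, 15), 1.0),
                (datetime(2016, 4, 30), 15.0),
            ],
            diurnal_amplitude=0.0, noise_sd=0.0,
        )
        s = simulate_field_series(cfg)
        scan = predictor.predict_planting_scan(
            make_model(TCURVE), s, 50.0, "2015-11-01", "2015-12-31"
        )
        result = predictor.spring_planting_date(scan, cutoff="2016-03-01")
        rec = result.iloc[0]
        assert rec["planting_date"] == pd.Timestamp("2015-11-01")

    def test_series_ending_before_cutoff_is_indeterminate(self):
        s = constant_series(start="2015-09-01", days=60, psi=-3.0)
        scan = predictor.predict_planting_scan(
            make_model(), s, 50.0, "2015-09-01", "2015-10-20"
        )
        result = predictor.spring_planting_date(scan, cutoff="2016-03-01")
        rec = result.iloc[0]
        assert rec["status"] == predictor.STATUS_INDETERMINATE
        assert pd.isna(rec["planting_date"])

    def test_non_germination_with_coverage_counts_as_met(self):
        # wet early autumn only; series runs past the cutoff
        cfg = FieldSimConfig(
            start=datetime(2015, 9, 1), end=datetime(2016, 3, 15),
            temp_trend=15.0, diurnal_amplitude=0.0, noise_sd=0.0,
            wet_windows=[(datetime(2015, 9, 1), datetime(2015, 9, 10))],
        )
        s = simulate_field_series(cfg)
        scan = predictor.predict_planting_scan(
            make_model(), s, 50.0, "2015-09-01", "2015-09-30"
        )
        result = predictor.spring_planting_date(scan, cutoff="2016-03-01")
        rec = result.iloc[0]
        assert rec["status"] == predictor.STATUS_MET_BY_NON_GERMINATION

    def test_default_cutoff_is_following_march_first(self):
        s = cooling_series()
        scan = predictor.predict_planting_scan(
            make_model(TCURVE), s, 50.0, "2015-09-01", "2016-02-28"
        )
        explicit = predictor.spring_planting_date(scan, cutoff="2016-03-01")
        default = predictor.spring_planting_date(scan)
        assert explicit.equals(default)

    def test_empty_scan_rejected(self):
        s = cooling_series()
        scan = predictor.predict_planting_scan(
            make_model(), s, 50.0, "2015-09-01", "2015-09-02"
        )
        scan.frame = scan.frame.iloc[0:0]
        with pytest.raises(ValueError):
            predictor.spring_planting_date(scan)
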