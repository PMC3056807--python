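import numpy as np
import pandas as pd
import pytest

from mdicp.cohort import CohortConfig, simulate_cohort
from mdicp.preprocess import (DEFAULT_LIMITS, PreprocessConfig, PreprocessReport,
                              align_pressures, apply_limiters, compute_ratios,
                              extract_complete_sets, preprocess_cohort,
                              shift_transfer_time, transform_markers)


def md_frame(times, **markers):
    df = pd.DataFrame({"vial_time": pd.to_datetime(times)})
    for m in ("glucose", "lactate", "pyruvate", "glycerol"):
        df[m] = markers.get(m, [1.0] * len(df))
    return df


class TestShiftTransferTime:
    def test_seventeen_minute_membrane_delay(self):
        df = shift_transfer_time(md_frame(["2021-01-01 12:00"]), 17)
        assert df["membrane_time"].iloc[0] == pd.Timestamp("2021-01-01 11:43")

    def test_zero_delay_is_identity(self):
        df = md_frame(["2021-01-01 12:00", "2021-01-01 13:00"])
        out = shift_transfer_time(df, 0)
        assert (out["membrane_time"] == out["vial_time"]).all()

    def test_shift_preserves_spacing(self):
        df = md_frame(["2021-01-01 12:00", "2021-01-01 13:00"])
        out = shift_transfer_time(df, 17)
        assert out["membrane_time"].diff().iloc[1] == pd.Timedelta(minutes=60)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            shift_transfer_time(md_frame(["2021-01-01 12:00"]), -1)


class TestLimiters:
    def test_out_of_range_clamped_and_logged(self):
        rep = PreprocessReport()
        df = md_frame(["2021-01-01 12:00"], glycerol=[9999.0])
        out = apply_limiters(df, report=rep)
        assert out["glycerol"].iloc[0] == DEFAULT_LIMITS["glycerol"][1]
        assert rep.clamped["glycerol"] == 1

    def test_in_range_is_identity(self):
        df = md_frame(["2021-01-01 12:00"], glucose=[2.0], lactate=[5.0],
                      pyruvate=[150.0], glycerol=[100.0])
        rep = PreprocessReport()
        out = apply_limiters(df, report=rep)
        pd.testing.assert_frame_equal(out, df)
        assert sum(rep.clamped.values()) == 0

    def test_limiters_are_idempotent(self):
        df = md_frame(["2021-01-01 12:00"], pyruvate=[3.0])
        once = apply_limiters(df)
        twice = apply_limiters(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_floored_pyruvate_bounds_lp_ratio(self):
        # pyruvate below the assay floor is clamped, so the LP ratio is
        # lactate*1000 / floor rather than blowing up
        df = md_frame(["2021-01-01 12:00"], lactate=[5.0], pyruvate=[0.5])
        out = compute_ratios(apply_limiters(df))
        floor = DEFAULT_LIMITS["pyruvate"][0]
        assert out["lp_ratio"].iloc[0] == pytest.approx(5000.0 / floor)


class TestRatios:
    @pytest.mark.parametrize("lactate,pyruvate,glucose,lp,lg", [
        (5.0, 200.0, 2.0, 25.0, 2.5),
        (3.0, 100.0, 1.0, 30.0, 3.0),
    ])
    def test_unit_harmonized_arithmetic(self, lactate, pyruvate, glucose, lp, lg):
        out = compute_ratios(md_frame(["2021-01-01 12:00"], lactate=[lactate],
                                      pyruvate=[pyruvate], glucose=[glucose]))
        assert out["lp_ratio"].iloc[0] == pytest.approx(lp)
        assert out["lg_ratio"].iloc[0] == pytest.approx(lg)

    def test_nonpositive_inputs_give_missing_ratios(self):
        out = compute_ratios(md_frame(["2021-01-01 12:00"], glucose=[np.nan]))
        assert np.isnan(out["lg_ratio"].iloc[0])


class TestTransforms:
    def test_square_root_and_log10(self):
        out = transform_markers(md_frame(["2021-01-01 12:00"], glucose=[4.0],
                                         glycerol=[100.0]))
        assert out["glucose_t"].iloc[0] == pytest.approx(2.0)
        assert out["glycerol_t"].iloc[0] == pytest.approx(2.0)

    def test_round_trip(self):
        from mdicp.cohort import from_modeling_scale, to_modeling_scale
        for m in ("lactate", "glycerol"):
            assert float(from_modeling_scale(m, to_modeling_scale(m, 7.3))
                         ) == pytest.approx(7.3)


def stream(times, values):
    return pd.DataFrame({"timestamp": pd.to_datetime(times), "value": values})


def minute_stream(start, minutes, values):
    times = pd.date_range(start, periods=minutes, freq="min")
    return pd.DataFrame({"timestamp": times, "value": values})


class TestAlignPressures:
    def test_constant_streams(self):
        md = shift_transfer_time(md_frame(["2021-01-01 13:00"]), 0)
        icp = minute_stream("2021-01-01 12:00", 61, [12.0] * 61)
        mp = minute_stream("2021-01-01 12:00", 61, [82.0] * 61)
        out = align_pressures(md, icp, mp)
        assert out["icp_hour"].iloc[0] == pytest.approx(12.0)
        assert out["cpp_hour"].iloc[0] == pytest.approx(70.0)

    def test_alternating_stream_mean(self):
        md = shift_transfer_time(md_frame(["2021-01-01 13:00"]), 0)
        vals = [10.0, 20.0] * 30
        icp = minute_stream("2021-01-01 12:01", 60, vals)
        mp = minute_stream("2021-01-01 12:01", 60, [80.0] * 60)
        out = align_pressures(md, icp, mp)
        assert out["icp_hour"].iloc[0] == pytest.approx(15.0)

    @pytest.mark.parametrize("gap_minutes,kept", [(30, True), (31, False)])
    def test_coverage_boundary(self, gap_minutes, kept):
        """A 30-min hole in the hour window sits exactly at 50% coverage
        (retained); one more missing minute drops the row."""
        md = shift_transfer_time(md_frame(["2021-01-01 13:00"]), 0)
        times = pd.date_range("2021-01-01 12:01", periods=60, freq="min")
        keep = times <= pd.Timestamp("2021-01-01 13:00") - pd.Timedelta(minutes=gap_minutes)
        icp = pd.DataFrame({"timestamp": times[keep], "value": 10.0})
        mp = pd.DataFrame({"timestamp": times[keep], "value": 80.0})
        # provide earlier context so the median sampling interval is 1 min
        ctx = pd.date_range("2021-01-01 10:00", periods=100, freq="min")
        icp = pd.concat([pd.DataFrame({"timestamp": ctx, "value": 10.0}), icp])
        mp = pd.concat([pd.DataFrame({"timestamp": ctx, "value": 80.0}), mp])
        rep = PreprocessReport()
        out = align_pressures(md, icp, mp, report=rep)
        assert (len(out) == 1) == kept
        if not kept:
            assert rep.dropped["pressure_coverage"] == 1

    def test_no_overlap_returns_empty_with_log(self):
        md = shift_transfer_time(md_frame(["2022-06-01 13:00"]), 0)
        icp = minute_stream("2021-01-01 12:00", 10, [10.0] * 10)
        mp = minute_stream("2021-01-01 12:00", 10, [80.0] * 10)
        rep = PreprocessReport()
        out = align_pressures(md, icp, mp, report=rep)
        assert len(out) == 0
        assert rep.dropped.get("pressure_coverage") == 1


class TestCompleteSets:
    def test_incomplete_rows_dropped_and_counted(self):
        df = md_frame([f"2021-01-01 {h:02d}:00" for h in range(10)])
        df.loc[[2, 5, 7], "glycerol"] = np.nan
        df["icp_hour"] = 10.0
        df["cpp_hour"] = 70.0
        rep = PreprocessReport()
        out = extract_complete_sets(df, rep)
        assert len(out) == 7
        assert rep.dropped["incomplete_set"] == 3

    def test_complete_frame_unchanged(self):
        df = md_frame(["2021-01-01 12:00"])
        df["icp_hour"] = 10.0
        df["cpp_hour"] = 70.0
        pd.testing.assert_frame_equal(extract_complete_sets(df), df)

    def test_idempotent(self):
        df = md_frame([f"2021-01-01 {h:02d}:00" for h in range(5)])
        df.loc[[1], "lactate"] = np.nan
        df["icp_hour"] = 10.0
        df["cpp_hour"] = 70.0
        once = extract_complete_sets(df)
        pd.testing.assert_frame_equal(extract_complete_sets(once), once)


class TestPipeline:
    def test_no_missingness_retains_all_vials(self):
        cfg = CohortConfig(n_patients=4, hours_mean=30, seed=5, missing_rate=0.0)
        records = simulate_cohort(cfg)
        frame, reports = preprocess_cohort(records, return_reports=True)
        assert len(frame) == sum(len(r.md_samples) for r in records)
        assert all(not r.dropped for r in reports.values())

    def test_row_counts_never_exceed_vials(self, small_records):
        frame, reports = preprocess_cohort(small_records, return_reports=True)
        for rec in small_records:
            rep = reports[rec.patient_id]
            assert rep.n_retained <= rep.n_vials
            assert rep.n_retained + sum(rep.dropped.values()) == rep.n_vials

    def test_artifact_exclusion_interval(self, small_records):
        rec = small_records[0]
        t0 = rec.md_samples["vial_time"].iloc[2]
        t1 = rec.md_samples["vial_time"].iloc[4]
        cfg = PreprocessConfig(exclusions=[(rec.patient_id, t0, t1)])
        frame, reports = preprocess_cohort([rec], cfg, return_reports=True)
        assert reports[rec.patient_id].dropped.get("artifact_exclusion", 0) >= 2
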