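"""Baseline creatinine estimation and KDIGO staging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from renal_angina.kdigo import (
    BaselineScr,
    BaselineSource,
    assess,
    baseline_scr,
    first_onset_any,
    stage_from_scr,
    stage_from_uo,
)
from renal_angina.records import Series

from conftest import make_patient


def series(*pts):
    t, v = zip(*pts) if pts else ((), ())
    return Series(np.array(t, float), np.array(v, float))


def final_stage(timeline):
    return timeline[-1][1] if timeline else 0


class TestBaseline:
    def test_measured_value_preferred(self):
        rec = make_patient(baseline_scr_umol_per_L=30.0, height_cm=120.0)
        bl = baseline_scr(rec)
        assert bl.value_umol_per_L == 30.0
        assert bl.source is BaselineSource.MEASURED_LOWEST_3MO

    def test_schwartz_backcalculation(self):
        # 0.413 * 120 cm / 120 = 0.413 mg/dL = 36.51 umol/L
        rec = make_patient(baseline_scr_umol_per_L=None, height_cm=120.0)
        bl = baseline_scr(rec)
        assert bl.source is BaselineSource.SCHWARTZ_ESTIMATED
        assert bl.value_umol_per_L == pytest.approx(36.51, abs=0.005)

    def test_no_baseline_no_height_errors(self):
        rec = make_patient(baseline_scr_umol_per_L=None, height_cm=None)
        with pytest.raises(ValueError, match="height"):
            baseline_scr(rec)


class TestScrStaging:
    @pytest.mark.parametrize(
        "pts,baseline,expected",
        [
            ([(6.0, 28.0)], 30.0, 0),  # decreased SCr
            ([(10.0, 62.0)], 30.0, 2),  # ratio 2.07
            ([(10.0, 45.0)], 30.0, 1),  # ratio 1.5 exactly
            ([(10.0, 44.9)], 30.0, 0),  # just under 1.5, no absolute rise
            ([(10.0, 91.0)], 30.0, 3),  # ratio >= 3
            ([(10.0, 360.0)], 200.0, 3),  # absolute >= 353.6 despite ratio 1.8
        ],
    )
    def test_ratio_bands(self, pts, baseline, expected):
        assert final_stage(stage_from_scr(series(*pts), baseline)) == expected

    def test_absolute_rise_within_48h_is_stage1(self):
        s = series((0.0, 100.0), (40.0, 130.0))
        assert final_stage(stage_from_scr(s, 100.0)) == 1

    def test_absolute_rise_outside_48h_ignored(self):
        s = series((0.0, 100.0), (50.0, 130.0))
        assert final_stage(stage_from_scr(s, 100.0)) == 0

    def test_rrt_forces_stage3_from_start_time(self):
        tl = stage_from_scr(series((5.0, 40.0)), 30.0, rrt_start_h=20.0)
        assert tl == [(5.0, 0), (20.0, 3)]

    def test_empty_series_stage0(self, caplog):
        with caplog.at_level("WARNING"):
            assert stage_from_scr(series(), 30.0) == []
        assert "empty" in caplog.text

    def test_stage_is_running_maximum(self):
        s = series((6.0, 70.0), (30.0, 31.0))
        tl = stage_from_scr(s, 30.0)
        assert tl == [(6.0, 2), (30.0, 2)]


class TestUoStaging:
    def rate_series(self, rate, hours, weight=10.0, step=1.0):
        pts = [(t, rate * weight * step) for t in np.arange(step, hours + 1e-9, step)]
        return series(*pts)

    def test_normal_rate_stage0(self):
        assert final_stage(stage_from_uo(self.rate_series(1.0, 24), 10.0)) == 0

    def test_oliguria_14h_stage2(self):
        tl = stage_from_uo(self.rate_series(0.4, 14), 10.0)
        assert final_stage(tl) == 2
        assert (6.0, 1) in tl and (12.0, 2) in tl

    def test_oliguria_8h_stage1_only(self):
        assert final_stage(stage_from_uo(self.rate_series(0.4, 8), 10.0)) == 1

    def test_severe_oliguria_24h_stage3(self):
        assert final_stage(stage_from_uo(self.rate_series(0.2, 24), 10.0)) == 3

    def test_anuria_12h_stage3(self):
        assert final_stage(stage_from_uo(self.rate_series(0.0, 12), 10.0)) == 3

    def test_interrupted_run_resets(self):
        pts = [(t, 0.4 * 10.0) for t in range(1, 8)] + [(8.0, 20.0)] + [
            (t, 0.4 * 10.0) for t in range(9, 16)
        ]
        assert final_stage(stage_from_uo(series(*pts), 10.0)) == 1

    def test_zero_weight_errors(self):
        with pytest.raises(ValueError, match="weight"):
            stage_from_uo(self.rate_series(1.0, 6), 0.0)


class TestAssess:
    def test_quiet_patient_stage0(self):
        rec = make_patient(scr=[(6.0, 28.0), (48.0, 29.0)], urine=[(12.0, 220.0), (24.0, 220.0)])
        a = assess(rec, BaselineScr(30.0, BaselineSource.MEASURED_LOWEST_3MO))
        assert a.stage_by_72h == 0 and not a.severe_aki
        assert a.first_aki_onset_h is None and a.first_severe_onset_h is None

    def test_max_combination_across_routes(self):
        # SCr stage 1 at 30 h; urine oliguria from 28 h crossing the 12 h
        # stage-2 duration at 40 h
        urine = [(t, 1.5 * 18.0) for t in np.arange(2.0, 28.1, 2.0)]
        urine += [(t, 0.4 * 18.0 * 2.0) for t in np.arange(30.0, 72.1, 2.0)]
        rec = make_patient(scr=[(30.0, 46.0)], urine=urine)
        a = assess(rec, BaselineScr(30.0, BaselineSource.MEASURED_LOWEST_3MO))
        assert a.stage_by_72h == 2 and a.severe_aki
        assert a.first_aki_onset_h == 30.0
        assert a.first_severe_onset_h == pytest.approx(40.0)

    def test_disabling_uo_never_raises_stage(self):
        urine = [(t, 0.2 * 18.0) for t in np.arange(1.0, 72.1, 1.0)]
        rec = make_patient(scr=[(30.0, 46.0)], urine=urine)
        bl = BaselineScr(30.0, BaselineSource.MEASURED_LOWEST_3MO)
        assert assess(rec, bl, use_uo=True).stage_by_72h >= assess(rec, bl, use_uo=False).stage_by_72h
        assert assess(rec, bl, use_uo=False).stage_by_72h == 1

    def test_first_onset_any_sees_past_72h(self):
        rec = make_patient(scr=[(24.0, 28.0), (80.0, 50.0)])
        bl = BaselineScr(30.0, BaselineSource.MEASURED_LOWEST_3MO)
        assert assess(rec, bl).stage_by_72h == 0
        assert first_onset_any(rec, bl) == 80.0

    @given(factor=st.floats(min_value=0.2, max_value=5.0))
    def test_ratio_bands_scale_invariant_below_absolute_cutoffs(self, factor):
        """Scaling SCr and baseline together preserves ratio-band stages
        when the absolute-value rules are not in play."""
        base = 10.0
        s = series((6.0, 21.0), (30.0, 25.0))  # ratios 2.1, 2.5; tiny rises
        scaled = Series(s.times, s.values * factor)
        if np.all(scaled.values < 353.6) and np.all(np.diff(scaled.values) < 26.5):
            assert final_stage(stage_from_scr(scaled, base * factor)) == final_stage(
                stage_from_scr(s, base)
            )

    def test_stage_monotone_in_scr(self):
        base = 30.0
        low = series((10.0, 50.0))
        high = series((10.0, 70.0))
        assert final_stage(stage_from_scr(high, base)) >= final_stage(stage_from_scr(low, base))


def test_synthetic_cohort_stage_split_tracks_configured_margins():
    """At large n the staged synthetic cohort reproduces the configured
    stage structure: ~80% any AKI, stage 3 dominant among the severe."""
    from renal_angina.pipeline import RunConfig, analyze_records
    from renal_angina.synthetic import GeneratorConfig, generate_trajectory_cohort

    recs = generate_trajectory_cohort(
        GeneratorConfig(n_patients=2000, seed=21), exclusion_counts=(0, 0, 0, 0)
    )
    res = analyze_records(recs, RunConfig("x", "y", "z"))
    f = res.summary.frame
    assert f["aki_any"].mean() == pytest.approx(53 / 66, abs=0.06)
    severe = f[f["severe_aki"]]
    assert (severe["stage"] == 3).mean() == pytest.approx(31 / 36, abs=0.06)
    assert f["severe_aki"].mean() == pytest.approx(36 / 66, abs=0.06)
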