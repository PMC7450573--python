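import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from renal_angina.fluid import FluidSummary
from renal_angina.kdigo import AKIAssessment
from renal_angina.rai import RAIResult
from renal_angina.records import PatientRecord, Series

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

T0 = pd.Timestamp("2016-01-01T00:00:00")


def make_patient(pid="p1", stay_h=120.0, **kw):
    """Minimal valid patient record; series and covariates via keywords."""
    series = {}
    for kind, key in (
        ("scr_umol_per_L", "scr"),
        ("urine_mL", "urine"),
        ("fluid_in_mL", "fluid_in"),
        ("fluid_out_mL", "fluid_out"),
    ):
        pts = kw.pop(key, None)
        if pts is not None:
            t, v = zip(*pts) if pts else ((), ())
            series[kind] = Series(np.array(t, float), np.array(v, float))
    defaults = dict(
        patient_id=pid,
        age_months=60.0,
        sex="male",
        admission_weight_kg=18.0,
        admission_time=T0,
        discharge_or_death_time=T0 + pd.Timedelta(hours=stay_h),
        known_kidney_disease=False,
        transplant=False,
        underlying_disease=False,
        lactate_mmol_per_L=2.0,
        died=False,
        height_cm=110.0,
        baseline_scr_umol_per_L=30.0,
    )
    for name in ("mv_start_h", "vs_start_h", "rrt_start_h"):
        off = kw.pop(name, None)
        if off is not None:
            kw[name.replace("_h", "_time")] = T0 + pd.Timedelta(hours=off)
    defaults.update(kw)
    return PatientRecord(series=series, **defaults)


def make_assessment(pid, stage=0, onset=None, severe_onset=None):
    return AKIAssessment(pid, stage, stage >= 2, onset, severe_onset)


def make_rai_result(pid, positive):
    if positive:
        return RAIResult(pid, 5, 2, 10, True)
    return RAIResult(pid, 1, 1, 1, False)


def make_fluid(pid, fo=0.0):
    return FluidSummary(pid, fo, fo > 10.0)


@pytest.fixture
def table3_rai():
    """RAI+ vs severe-AKI 2x2 from the analysed cohort (30/36 vs 8/30)."""
    from renal_angina.stats import ContingencyTable

    return ContingencyTable(a=30, b=8, c=6, d=22)


@pytest.fixture
def table3_scr():
    """SCr>base vs severe-AKI 2x2 (28/36 vs 11/30)."""
    from renal_angina.stats import ContingencyTable

    return ContingencyTable(a=28, b=11, c=8, d=19)
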