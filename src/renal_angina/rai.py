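"""Renal angina index (RAI).

The RAI stratifies critically ill children for risk of subsequent severe
acute kidney injury.  It is the product of a *risk* tier and an *injury*
tier, assessed on clinical data from the first 12 h of PICU admission:

Risk tier (the highest applicable applies; tiers do not sum):

====  =============================================================
 1    admission to the PICU
 3    solid-organ or stem-cell transplantation
 5    mechanical ventilation or vasoactive support (or both)
====  =============================================================

Injury tier — the worse of a creatinine band and a fluid-overload band:

====  ===========================  =================
tier  SCr / baseline               % fluid overload
====  ===========================  =================
 1    decreased or no change       < 5 %
 2    > 1× – 1.49×                 5 – < 10 %
 4    1.5× – 1.99×                 10 – 15 %
 8    ≥ 2×                         > 15 %
====  ===========================  =================

The index therefore ranges over {1,2,3,4,5,6,8,10,12,20,24,40} ⊂ [1, 40];
an index ≥ 8 is "renal angina positive" (RAI+).  Note the injury strata
reward creatinine changes smaller than the 1.5× that KDIGO stage 1
requires: any elevation above baseline already scores 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .fluid import FluidSummary
from .kdigo import BaselineScr
from .records import PatientRecord

RAI_POSITIVE_THRESHOLD = 8
RISK_TIERS = (1, 3, 5)
INJURY_TIERS = (1, 2, 4, 8)
VALID_RAI_VALUES = frozenset(r * i for r in RISK_TIERS for i in INJURY_TIERS)


@dataclass(frozen=True)
class RAIInput:
    """Inputs to the index, all assessed over the first 12 h of admission."""

    patient_id: str
    picu_admission: bool
    transplant: bool
    mv_within_12h: bool
    vs_within_12h: bool
    scr_ratio: float  # max SCr in first 12 h / baseline
    fo_percent: float

    def __post_init__(self) -> None:
        if self.scr_ratio <= 0:
            raise ValueError("scr_ratio must be positive")


@dataclass(frozen=True)
class RAIResult:
    patient_id: str
    risk_score: int
    injury_score: int
    rai: int
    rai_positive: bool

    def __post_init__(self) -> None:
        if self.risk_score not in RISK_TIERS:
            raise ValueError("risk score must be one of 1, 3, 5")
        if self.injury_score not in INJURY_TIERS:
            raise ValueError("injury score must be one of 1, 2, 4, 8")
        if self.rai != self.risk_score * self.injury_score:
            raise ValueError("rai must equal risk × injury")
        if self.rai_positive != (self.rai >= RAI_POSITIVE_THRESHOLD):
            raise ValueError("rai_positive must hold exactly when rai >= 8")


def risk_score(inp: RAIInput) -> int:
    """Highest applicable risk tier."""
    if not inp.picu_admission:
        raise ValueError("risk tiers are defined for PICU admissions")
    if inp.mv_within_12h or inp.vs_within_12h:
        return 5
    if inp.transplant:
        return 3
    return 1


def scr_injury_score(scr_ratio: float) -> int:
    """Creatinine injury band from the 12 h max-SCr / baseline ratio."""
    if scr_ratio <= 0:
        raise ValueError("scr_ratio must be positive")
    if scr_ratio >= 2.0:
        return 8
    if scr_ratio >= 1.5:
        return 4
    if scr_ratio > 1.0:
        return 2
    return 1


def fo_injury_score(fo_percent: float) -> int:
    """Fluid-overload injury band.

    Band edges: [5, 10) → 2, [10, 15] → 4, and strictly > 15 % → 8 (the
    top band is printed as "> 15%", so exactly 15 % scores 4).
    """
    if fo_percent > 15.0:
        return 8
    if fo_percent >= 10.0:
        return 4
    if fo_percent >= 5.0:
        return 2
    return 1


def compute_rai(inp: RAIInput) -> RAIResult:
    """Risk tier × worse injury band, with positivity at index ≥ 8."""
    risk = risk_score(inp)
    injury = max(scr_injury_score(inp.scr_ratio), fo_injury_score(inp.fo_percent))
    rai = risk * injury
    return RAIResult(inp.patient_id, risk, injury, rai, rai >= RAI_POSITIVE_THRESHOLD)


def rai_input_from_record(
    record: PatientRecord,
    baseline: BaselineScr,
    fluid_summary: FluidSummary,
    window_h: float = 12.0,
) -> RAIInput:
    """Assemble index inputs from a patient record.

    The creatinine ratio uses the maximum SCr measured in [0, window_h]
    over the baseline; with no early measurement the ratio defaults to 1.0
    (no documented change).  Support flags are true when therapy started at
    or before window_h.
    """
    early = record.scr_series.clip(window_h)
    ratio = float(early.values.max() / baseline.value_umol_per_L) if len(early) else 1.0

    def within(offset: Optional[float]) -> bool:
        return offset is not None and offset <= window_h

    return RAIInput(
        patient_id=record.patient_id,
        picu_admission=True,
        transplant=record.transplant,
        mv_within_12h=within(record.mv_offset_h),
        vs_within_12h=within(record.vs_offset_h),
        scr_ratio=ratio,
        fo_percent=fluid_summary.fo_percent,
    )
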