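"""Baseline creatinine estimation and 2012 KDIGO AKI staging.

Staging follows the 2012 KDIGO consensus criteria on a 0–3 scale.  Serum
creatinine (SCr) criteria, evaluated at each measurement time relative to a
per-patient baseline:

* stage 1 — SCr/baseline in [1.5, 2.0), or an absolute rise ≥ 26.5 µmol/L
  (0.3 mg/dL) between any two measurements at most 48 h apart;
* stage 2 — ratio in [2.0, 3.0);
* stage 3 — ratio ≥ 3.0, or SCr ≥ 353.6 µmol/L (4.0 mg/dL), or renal
  replacement therapy initiated.

Urine-output criteria, on hourly rates (mL/kg/h) over recorded intervals:

* stage 1 — rate < 0.5 sustained 6–12 h;
* stage 2 — rate < 0.5 sustained ≥ 12 h;
* stage 3 — rate < 0.3 sustained ≥ 24 h, or anuria ≥ 12 h.

The stage at a time t is the running maximum over both routes; severe AKI
means stage ≥ 2 reached within the 72 h observation window.

Baseline SCr is the lowest measured value in the 3 months before admission
when available, otherwise back-calculated from height via the bedside
Schwartz formula at an assumed eGFR of 120 mL/min/1.73 m²:
``SCr[mg/dL] = k · height[cm] / 120`` with k = 0.413, converted to µmol/L
by the factor 88.4.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .records import PatientRecord, Series

logger = logging.getLogger(__name__)

MGDL_TO_UMOL = 88.4
SCHWARTZ_K = 0.413
ASSUMED_EGFR = 120.0
ABS_RISE_UMOL = 26.5  # 0.3 mg/dL
STAGE3_ABS_UMOL = 353.6  # 4.0 mg/dL
ABS_RISE_WINDOW_H = 48.0


class BaselineSource(str, enum.Enum):
    MEASURED_LOWEST_3MO = "measured_lowest_3mo"
    SCHWARTZ_ESTIMATED = "schwartz_estimated"


@dataclass(frozen=True)
class BaselineScr:
    value_umol_per_L: float
    source: BaselineSource

    def __post_init__(self) -> None:
        if self.value_umol_per_L <= 0:
            raise ValueError("baseline creatinine must be positive")


@dataclass(frozen=True)
class AKIAssessment:
    """Per-patient staging over the 72 h observation window."""

    patient_id: str
    stage_by_72h: int
    severe_aki: bool
    first_aki_onset_h: Optional[float]
    first_severe_onset_h: Optional[float]

    def __post_init__(self) -> None:
        if not 0 <= self.stage_by_72h <= 3:
            raise ValueError("stage must be in 0..3")
        if self.severe_aki != (self.stage_by_72h >= 2):
            raise ValueError("severe_aki must hold exactly when stage >= 2")
        for t in (self.first_aki_onset_h, self.first_severe_onset_h):
            if t is not None and not (0 <= t <= 72.0):
                raise ValueError("onset times must lie in [0, 72]")


def baseline_scr(record: PatientRecord, k: float = SCHWARTZ_K) -> BaselineScr:
    """Baseline creatinine: measured pre-admission value, else Schwartz back-calculation."""
    if record.baseline_scr_umol_per_L is not None:
        return BaselineScr(record.baseline_scr_umol_per_L, BaselineSource.MEASURED_LOWEST_3MO)
    if record.height_cm is None:
        raise ValueError(
            f"{record.patient_id}: no measured baseline creatinine and no height "
            "for Schwartz estimation"
        )
    mg_dl = k * record.height_cm / ASSUMED_EGFR
    return BaselineScr(mg_dl * MGDL_TO_UMOL, BaselineSource.SCHWARTZ_ESTIMATED)


# ---------------------------------------------------------------------------
# staging

StageTimeline = list  # list[tuple[float, int]] — (time_h, running-max stage)


def stage_from_scr(
    scr_series: Series,
    baseline: float,
    window_end_h: float = 72.0,
    rrt_start_h: Optional[float] = None,
) -> StageTimeline:
    """Creatinine-route stage timeline (running maximum) on [0, window_end_h].

    Evaluation times are the measurement times plus, if present, the RRT
    start.  The 48 h absolute-rise rule is evaluated over all pairs of
    measurements at most 48 h apart (series are short; brute force).
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    s = scr_series.clip(window_end_h)
    if len(s) == 0 and (rrt_start_h is None or rrt_start_h > window_end_h):
        logger.warning("empty creatinine series: creatinine-route stage is 0")
        return []
    events: list[tuple[float, int]] = []
    t_arr, v_arr = s.times, s.values
    for i in range(len(s)):
        t, v = float(t_arr[i]), float(v_arr[i])
        ratio = v / baseline
        stage = 0
        if ratio >= 3.0 or v >= STAGE3_ABS_UMOL:
            stage = 3
        elif ratio >= 2.0:
            stage = 2
        elif ratio >= 1.5:
            stage = 1
        else:
            rose = np.any(
                (t - t_arr[: i + 1] <= ABS_RISE_WINDOW_H) & (v - v_arr[: i + 1] >= ABS_RISE_UMOL)
            )
            if rose:
                stage = 1
        events.append((t, stage))
    if rrt_start_h is not None and rrt_start_h <= window_end_h:
        events.append((max(rrt_start_h, 0.0), 3))
    events.sort(key=lambda e: e[0])
    timeline: StageTimeline = []
    running = 0
    for t, stage in events:
        running = max(running, stage)
        timeline.append((t, running))
    return timeline


def stage_from_uo(
    uo_series: Series, weight_kg: float, window_end_h: float = 72.0
) -> StageTimeline:
    """Urine-output-route stage timeline on [0, window_end_h].

    A volume recorded at offset t covers the interval since the previous
    recording (the first interval starts at admission).  A criterion is
    credited at the instant its required duration is first attained.
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    s = uo_series.clip(window_end_h)
    if len(s) == 0:
        return []
    starts = np.concatenate([[0.0], s.times[:-1]])
    durations = s.times - starts
    if np.any(durations <= 0):
        raise ValueError("urine recordings must have strictly increasing offsets")
    rates = s.values / durations / weight_kg  # mL/kg/h

    events: list[tuple[float, int]] = []

    def scan(pred, min_duration: float, stage: int) -> None:
        run_start = None
        run_end = None
        fired = False
        for t0, t1, ok in zip(starts, s.times, pred):
            if ok:
                if run_start is None or t0 != run_end:
                    run_start, fired = t0, False
                run_end = t1
                if not fired and run_end - run_start >= min_duration:
                    events.append((run_start + min_duration, stage))
                    fired = True
            else:
                run_start = None
        _ = run_end

    scan(rates < 0.5, 6.0, 1)
    scan(rates < 0.5, 12.0, 2)
    scan(rates < 0.3, 24.0, 3)
    scan(rates <= 0.0, 12.0, 3)

    events.sort(key=lambda e: e[0])
    timeline: StageTimeline = []
    running = 0
    for t, stage in events:
        if t > window_end_h:
            continue
        running = max(running, stage)
        timeline.append((t, running))
    return timeline


def _merge(timelines: list[StageTimeline]) -> StageTimeline:
    events = sorted(e for tl in timelines for e in tl)
    merged: StageTimeline = []
    running = 0
    for t, stage in events:
        running = max(running, stage)
        merged.append((t, running))
    return merged


def _first_at_least(timeline: StageTimeline, stage: int) -> Optional[float]:
    for t, s in timeline:
        if s >= stage:
            return t
    return None


def assess(
    record: PatientRecord,
    baseline: BaselineScr,
    window_end_h: float = 72.0,
    use_uo: bool = True,
) -> AKIAssessment:
    """Combined creatinine + urine-output assessment over [0, window_end_h].

    The urine route is skipped when ``use_uo`` is false or no urine data
    exist; removing it can never increase the stage.
    """
    timelines = [
        stage_from_scr(
            record.scr_series, baseline.value_umol_per_L, window_end_h, record.rrt_offset_h
        )
    ]
    if use_uo and len(record.urine_series):
        timelines.append(stage_from_uo(record.urine_series, record.admission_weight_kg, window_end_h))
    merged = _merge(timelines)
    stage = merged[-1][1] if merged else 0
    return AKIAssessment(
        patient_id=record.patient_id,
        stage_by_72h=stage,
        severe_aki=stage >= 2,
        first_aki_onset_h=_first_at_least(merged, 1),
        first_severe_onset_h=_first_at_least(merged, 2),
    )


def first_onset_any(
    record: PatientRecord, baseline: BaselineScr, use_uo: bool = True
) -> Optional[float]:
    """First time any stage ≥1 criterion is met over the *entire* series.

    Unlike :func:`assess`, this looks past 72 h; it exists to let the
    eligibility filter tell "no AKI at all" apart from "AKI first arising
    after day 3".
    """
    end = np.inf
    timelines = [
        stage_from_scr(record.scr_series, baseline.value_umol_per_L, end, record.rrt_offset_h)
    ]
    if use_uo and len(record.urine_series):
        timelines.append(stage_from_uo(record.urine_series, record.admission_weight_kg, end))
    return _first_at_least(_merge(timelines), 1)
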