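"""Patient data model, cohort table IO and the eligibility filter.

The cohort is exchanged as two delimited text files:

``cohort.csv``
    One row per patient: demographics, admission/discharge timestamps,
    support-therapy onset timestamps (mechanical ventilation, vasoactive
    support, renal replacement therapy), an optional measured baseline
    creatinine, and numeric covariates.  Unknown columns are preserved as
    opaque covariates.

``timeseries.csv``
    Long format ``patient_id,time_offset_h,kind,value`` with one row per
    measurement.  ``time_offset_h`` is hours since PICU admission; ``kind``
    is one of ``scr_umol_per_L`` (serum creatinine), ``urine_mL`` (urine
    volume over the interval ending at the offset), ``fluid_in_mL`` and
    ``fluid_out_mL`` (fluid volumes over the interval ending at the offset).

All analysis windows ("within 12 h", "within 24 h", "within 3 days") are
closed intervals measured in hours from admission.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .kdigo import AKIAssessment

SERIES_KINDS = ("scr_umol_per_L", "urine_mL", "fluid_in_mL", "fluid_out_mL")

#: mandatory cohort.csv columns
MANDATORY_COLUMNS = (
    "patient_id",
    "age_months",
    "sex",
    "admission_weight_kg",
    "admission_time",
    "discharge_or_death_time",
    "known_kidney_disease",
    "transplant",
    "underlying_disease",
    "lactate_mmol_per_L",
    "died",
)

OPTIONAL_NUMERIC_COLUMNS = (
    "height_cm",
    "baseline_scr_umol_per_L",
    "albumin_g_per_L",
    "aptt_s",
    "platelet_1e9_per_L",
    "prism3",
    "pelod2",
)

OPTIONAL_TIME_COLUMNS = ("mv_start_time", "vs_start_time", "rrt_start_time")


@dataclass
class Series:
    """A time-sorted measurement series: hours since admission and values."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size and not np.all(np.diff(self.times) >= 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.values = self.values[order]
        if np.any(self.times < 0) or not np.all(np.isfinite(self.times)):
            raise ValueError("time offsets must be finite and non-negative")
        if np.any(self.values < 0):
            raise ValueError("series values must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)

    def clip(self, window_end_h: float) -> "Series":
        keep = self.times <= window_end_h
        return Series(self.times[keep], self.values[keep])


def empty_series() -> Series:
    return Series(np.empty(0), np.empty(0))


@dataclass
class PatientRecord:
    """One patient's covariates, support flags and measurement series."""

    patient_id: str
    age_months: float
    sex: str  # "male" | "female"
    admission_weight_kg: float
    admission_time: pd.Timestamp
    discharge_or_death_time: pd.Timestamp
    known_kidney_disease: bool
    transplant: bool
    underlying_disease: bool
    lactate_mmol_per_L: float
    died: bool
    height_cm: Optional[float] = None
    baseline_scr_umol_per_L: Optional[float] = None
    mv_start_time: Optional[pd.Timestamp] = None
    vs_start_time: Optional[pd.Timestamp] = None
    rrt_start_time: Optional[pd.Timestamp] = None
    albumin_g_per_L: Optional[float] = None
    aptt_s: Optional[float] = None
    platelet_1e9_per_L: Optional[float] = None
    prism3: Optional[float] = None
    pelod2: Optional[float] = None
    extra: dict = field(default_factory=dict)
    series: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (1.0 <= self.age_months <= 192.0):
            raise ValueError(
                f"{self.patient_id}: age_months {self.age_months} outside cohort "
                "definition of 1 month to 16 years"
            )
        if self.admission_weight_kg <= 0:
            raise ValueError(f"{self.patient_id}: non-positive admission weight")
        if self.admission_time > self.discharge_or_death_time:
            raise ValueError(f"{self.patient_id}: admission after discharge/death")
        for name in ("height_cm", "baseline_scr_umol_per_L", "lactate_mmol_per_L"):
            v = getattr(self, name)
            if v is not None and name != "lactate_mmol_per_L" and v <= 0:
                raise ValueError(f"{self.patient_id}: {name} must be positive")
        if self.lactate_mmol_per_L < 0:
            raise ValueError(f"{self.patient_id}: negative lactate")
        for kind in SERIES_KINDS:
            self.series.setdefault(kind, empty_series())

    # -- derived time offsets (hours since admission) ---------------------
    def _offset(self, ts: Optional[pd.Timestamp]) -> Optional[float]:
        if ts is None or pd.isna(ts):
            return None
        return (ts - self.admission_time) / pd.Timedelta(hours=1)

    @property
    def stay_h(self) -> float:
        return (self.discharge_or_death_time - self.admission_time) / pd.Timedelta(hours=1)

    @property
    def mv_offset_h(self) -> Optional[float]:
        return self._offset(self.mv_start_time)

    @property
    def vs_offset_h(self) -> Optional[float]:
        return self._offset(self.vs_start_time)

    @property
    def rrt_offset_h(self) -> Optional[float]:
        return self._offset(self.rrt_start_time)

    @property
    def scr_series(self) -> Series:
        return self.series["scr_umol_per_L"]

    @property
    def urine_series(self) -> Series:
        return self.series["urine_mL"]

    @property
    def fluid_in_series(self) -> Series:
        return self.series["fluid_in_mL"]

    @property
    def fluid_out_series(self) -> Series:
        return self.series["fluid_out_mL"]


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    STAY_LT_48H = "stay_lt_48h"
    KNOWN_KIDNEY_DISEASE = "known_kidney_disease"
    AKI_ONSET_AFTER_DAY3 = "aki_onset_after_day3"
    SEVERE_AKI_WITHIN_12H = "severe_aki_within_12h"


@dataclass(frozen=True)
class EligibilityDecision:
    patient_id: str
    eligible: bool
    exclusion_reason: ExclusionReason

    def __post_init__(self) -> None:
        if self.eligible != (self.exclusion_reason is ExclusionReason.NONE):
            raise ValueError("eligible must hold exactly when the reason is 'none'")


# ---------------------------------------------------------------------------
# reading and writing


def _parse_bool(v, row: int, col: str) -> bool:
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise ValueError(f"row {row}: cannot parse boolean {col}={v!r}")


def _parse_time(v, row: int, col: str) -> Optional[pd.Timestamp]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
        return None
    try:
        ts = pd.Timestamp(str(v))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"row {row}: unparseable timestamp {col}={v!r}") from exc
    if pd.isna(ts):
        return None
    return ts


def _parse_optional_float(v, row: int, col: str) -> Optional[float]:
    if v is None or str(v).strip() == "":
        return None
    try:
        x = float(v)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"row {row}: cannot parse number {col}={v!r}") from exc
    if np.isnan(x):
        return None
    return x


def read_cohort(covariate_table_path, timeseries_table_path) -> list[PatientRecord]:
    """Read ``cohort.csv`` + ``timeseries.csv`` into PatientRecords.

    Raises ``ValueError`` naming the offending id / row / column on duplicate
    patient ids, unparseable timestamps, negative measurement values or a
    missing mandatory column, and ``FileNotFoundError`` for missing files.
    """
    cov = pd.read_csv(covariate_table_path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in cov.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    ids = cov["patient_id"].tolist()
    dupes = pd.Series(ids)[pd.Series(ids).duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate patient_id: {', '.join(map(str, dupes))}")

    known = set(MANDATORY_COLUMNS) | set(OPTIONAL_NUMERIC_COLUMNS) | set(OPTIONAL_TIME_COLUMNS)
    extra_cols = [c for c in cov.columns if c not in known]

    records: list[PatientRecord] = []
    for i, row in enumerate(cov.itertuples(index=False), start=2):  # header = row 1
        row = row._asdict()
        kwargs = dict(
            patient_id=str(row["patient_id"]),
            age_months=float(row["age_months"]),
            sex=str(row["sex"]).strip().lower(),
            admission_weight_kg=float(row["admission_weight_kg"]),
            admission_time=_parse_time(row["admission_time"], i, "admission_time"),
            discharge_or_death_time=_parse_time(
                row["discharge_or_death_time"], i, "discharge_or_death_time"
            ),
            known_kidney_disease=_parse_bool(row["known_kidney_disease"], i, "known_kidney_disease"),
            transplant=_parse_bool(row["transplant"], i, "transplant"),
            underlying_disease=_parse_bool(row["underlying_disease"], i, "underlying_disease"),
            lactate_mmol_per_L=float(row["lactate_mmol_per_L"]),
            died=_parse_bool(row["died"], i, "died"),
        )
        if kwargs["admission_time"] is None or kwargs["discharge_or_death_time"] is None:
            raise ValueError(f"row {i}: admission and discharge/death timestamps are mandatory")
        for col in OPTIONAL_NUMERIC_COLUMNS:
            if col in row:
                kwargs[col] = _parse_optional_float(row[col], i, col)
        for col in OPTIONAL_TIME_COLUMNS:
            if col in row:
                kwargs[col] = _parse_time(row[col], i, col)
        kwargs["extra"] = {c: row[c] for c in extra_cols}
        records.append(PatientRecord(**kwargs))

    _attach_series(records, timeseries_table_path)
    return records


def _attach_series(records: Sequence[PatientRecord], timeseries_table_path) -> None:
    ts = pd.read_csv(timeseries_table_path, dtype=str, keep_default_na=False)
    needed = ("patient_id", "time_offset_h", "kind", "value")
    missing = [c for c in needed if c not in ts.columns]
    if missing:
        raise ValueError(f"timeseries: missing mandatory column(s): {', '.join(missing)}")
    by_id = {r.patient_id: r for r in records}
    if len(ts) == 0:
        return
    times = pd.to_numeric(ts["time_offset_h"], errors="coerce").to_numpy()
    values = pd.to_numeric(ts["value"], errors="coerce").to_numpy()
    for idx in np.flatnonzero(~np.isfinite(times) | ~np.isfinite(values)):
        raise ValueError(f"timeseries row {idx + 2}: unparseable or non-finite number")
    neg = np.flatnonzero((times < 0) | (values < 0))
    if neg.size:
        raise ValueError(f"timeseries row {neg[0] + 2}: negative time or value")
    frame = pd.DataFrame(
        {"patient_id": ts["patient_id"], "kind": ts["kind"], "t": times, "v": values}
    )
    bad_kind = set(frame["kind"]) - set(SERIES_KINDS)
    if bad_kind:
        raise ValueError(f"timeseries: unknown kind(s): {', '.join(sorted(bad_kind))}")
    for (pid, kind), grp in frame.groupby(["patient_id", "kind"], sort=False):
        rec = by_id.get(str(pid))
        if rec is None:
            raise ValueError(f"timeseries references unknown patient_id {pid!r}")
        grp = grp.sort_values("t", kind="stable")
        rec.series[str(kind)] = Series(grp["t"].to_numpy(), grp["v"].to_numpy())


def _fmt_time(ts: Optional[pd.Timestamp]) -> str:
    return "" if ts is None else ts.isoformat()


def _fmt_opt(v: Optional[float]) -> str:
    return "" if v is None else format(float(v), "g")


def write_cohort(records: Iterable[PatientRecord], covariate_table_path, timeseries_table_path) -> None:
    """Write records back out in the documented two-file schema."""
    rows = []
    extra_cols: list[str] = []
    records = list(records)
    for r in records:
        for c in r.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "age_months": format(r.age_months, "g"),
            "sex": r.sex,
            "admission_weight_kg": format(r.admission_weight_kg, "g"),
            "height_cm": _fmt_opt(r.height_cm),
            "admission_time": _fmt_time(r.admission_time),
            "discharge_or_death_time": _fmt_time(r.discharge_or_death_time),
            "known_kidney_disease": str(r.known_kidney_disease).lower(),
            "transplant": str(r.transplant).lower(),
            "underlying_disease": str(r.underlying_disease).lower(),
            "mv_start_time": _fmt_time(r.mv_start_time),
            "vs_start_time": _fmt_time(r.vs_start_time),
            "rrt_start_time": _fmt_time(r.rrt_start_time),
            "baseline_scr_umol_per_L": _fmt_opt(r.baseline_scr_umol_per_L),
            "lactate_mmol_per_L": format(r.lactate_mmol_per_L, "g"),
            "albumin_g_per_L": _fmt_opt(r.albumin_g_per_L),
            "aptt_s": _fmt_opt(r.aptt_s),
            "platelet_1e9_per_L": _fmt_opt(r.platelet_1e9_per_L),
            "prism3": _fmt_opt(r.prism3),
            "pelod2": _fmt_opt(r.pelod2),
            "died": str(r.died).lower(),
        }
        for c in extra_cols:
            row[c] = r.extra.get(c, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(covariate_table_path, index=False)

    ts_rows = []
    for r in records:
        for kind in SERIES_KINDS:
            s = r.series[kind]
            for t, v in zip(s.times, s.values):
                ts_rows.append(
                    {
                        "patient_id": r.patient_id,
                        "time_offset_h": format(float(t), "g"),
                        "kind": kind,
                        "value": format(float(v), "g"),
                    }
                )
    pd.DataFrame(ts_rows, columns=["patient_id", "time_offset_h", "kind", "value"]).to_csv(
        timeseries_table_path, index=False
    )


# ---------------------------------------------------------------------------
# eligibility


def apply_eligibility(
    records: Sequence[PatientRecord],
    aki_assessments: Mapping[str, "AKIAssessment"],
    first_onset_any_h: Optional[Mapping[str, Optional[float]]] = None,
) -> list[EligibilityDecision]:
    """Apply the cohort eligibility filter.

    Exclusions, in fixed precedence order (the first matching reason wins):

    1. hospital stay shorter than 48 h,
    2. previously known kidney disease,
    3. first AKI onset strictly after 72 h (requires ``first_onset_any_h``,
       the first time any stage ≥1 criterion is met over the *full* series,
       which may exceed the 72 h assessment window),
    4. severe AKI (KDIGO stage ≥2) reached at or before 12 h.

    All other patients are eligible.
    """
    decisions = []
    for rec in records:
        if rec.patient_id not in aki_assessments:
            raise ValueError(f"missing AKI assessment for patient {rec.patient_id}")
        a = aki_assessments[rec.patient_id]
        onset_any = a.first_aki_onset_h
        if first_onset_any_h is not None and rec.patient_id in first_onset_any_h:
            onset_any = first_onset_any_h[rec.patient_id]

        if rec.stay_h < 48.0:
            reason = ExclusionReason.STAY_LT_48H
        elif rec.known_kidney_disease:
            reason = ExclusionReason.KNOWN_KIDNEY_DISEASE
        elif onset_any is not None and onset_any > 72.0:
            reason = ExclusionReason.AKI_ONSET_AFTER_DAY3
        elif a.first_severe_onset_h is not None and a.first_severe_onset_h <= 12.0:
            reason = ExclusionReason.SEVERE_AKI_WITHIN_12H
        else:
            reason = ExclusionReason.NONE
        decisions.append(
            EligibilityDecision(rec.patient_id, reason is ExclusionReason.NONE, reason)
        )
    return decisions
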