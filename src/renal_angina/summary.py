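"""Group-comparison summary tables for the analysed cohort.

Builds the four comparison surfaces the analysis reports:

* survivors vs non-survivors (AKI stage distribution and early indicators),
* severe-AKI vs non-severe groups (baseline labs, severity, outcomes),
* RAI− vs RAI+ groups,
* the three early-warning groups (RAI+, SCr>base, FO+) side by side.

Binary variables are reported as count (%) and compared by Pearson
chi-square with a Fisher fallback; symmetric continuous covariates as
mean ± SD with Student's t; skewed covariates as median (IQR) with the
Wilcoxon rank-sum test (Kruskal–Wallis / one-way ANOVA across three
groups).  Percentages always re-derive exactly from the stored numerator
and denominator columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fluid import FluidSummary
from .kdigo import AKIAssessment
from .rai import RAIResult
from .records import PatientRecord
from .stats import ContingencyTable, chi_square_test, rank_compare, t_compare

# variable name -> summary kind
BINARY, NORMAL, SKEWED = "binary", "normal", "skewed"

_VARIABLES: list[tuple[str, str]] = [
    ("male", BINARY),
    ("underlying_disease", BINARY),
    ("age_months", SKEWED),
    ("scr_gt_base", BINARY),
    ("rai_positive", BINARY),
    ("fo_positive", BINARY),
    ("albumin_g_per_L", NORMAL),
    ("lactate_mmol_per_L", SKEWED),
    ("aptt_s", SKEWED),
    ("platelet_1e9_per_L", SKEWED),
    ("prism3", SKEWED),
    ("pelod2", SKEWED),
    ("mv", BINARY),
    ("rrt", BINARY),
    ("vs", BINARY),
    ("stage_0", BINARY),
    ("stage_1", BINARY),
    ("stage_2", BINARY),
    ("stage_3", BINARY),
    ("severe_aki", BINARY),
    ("died", BINARY),
]


@dataclass
class CohortSummary:
    """The four comparison tables plus the patient-level analysis frame."""

    frame: pd.DataFrame
    tables: dict


def assemble_analysis_frame(
    records: Sequence[PatientRecord],
    assessments: Mapping[str, AKIAssessment],
    rai_results: Mapping[str, RAIResult],
    fluid_summaries: Mapping[str, FluidSummary],
) -> pd.DataFrame:
    """One row per patient with every derived indicator the analysis uses."""
    rows = []
    for r in records:
        a = assessments[r.patient_id]
        rr = rai_results[r.patient_id]
        f = fluid_summaries[r.patient_id]
        rows.append(
            {
                "patient_id": r.patient_id,
                "age_months": r.age_months,
                "male": r.sex == "male",
                "underlying_disease": r.underlying_disease,
                "stage": a.stage_by_72h,
                "stage_0": a.stage_by_72h == 0,
                "stage_1": a.stage_by_72h == 1,
                "stage_2": a.stage_by_72h == 2,
                "stage_3": a.stage_by_72h == 3,
                "severe_aki": a.severe_aki,
                "aki_any": a.stage_by_72h >= 1,
                "rai": rr.rai,
                "rai_positive": rr.rai_positive,
                "scr_ratio_12h": rr.rai,  # placeholder replaced below if available
                "fo_percent": f.fo_percent,
                "fo_positive": f.fo_positive,
                "mv": r.mv_offset_h is not None and r.mv_offset_h <= 12.0,
                "vs": r.vs_offset_h is not None and r.vs_offset_h <= 12.0,
                "rrt": r.rrt_offset_h is not None,
                "died": r.died,
                "lactate_mmol_per_L": r.lactate_mmol_per_L,
                "albumin_g_per_L": r.albumin_g_per_L,
                "aptt_s": r.aptt_s,
                "platelet_1e9_per_L": r.platelet_1e9_per_L,
                "prism3": r.prism3,
                "pelod2": r.pelod2,
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.drop(columns=["scr_ratio_12h"])
    return frame


def attach_scr_gt_base(frame: pd.DataFrame, scr_ratios: Mapping[str, float]) -> pd.DataFrame:
    """Add the early creatinine-elevation indicator (12 h max SCr > baseline)."""
    frame = frame.copy()
    frame["scr_ratio_12h"] = frame["patient_id"].map(scr_ratios)
    frame["scr_gt_base"] = frame["scr_ratio_12h"] > 1.0
    return frame


def _round2(x: float) -> str:
    """Render half-up to two decimals (internal computation stays full precision)."""
    from decimal import ROUND_HALF_UP, Decimal

    return str(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _fmt_binary(num: int, den: int) -> str:
    pct = 100.0 * num / den if den else float("nan")
    return f"{num} ({_round2(pct)})"


def _fmt_normal(x: np.ndarray) -> str:
    if x.size > 1:
        return f"{_round2(np.mean(x))} ± {_round2(np.std(x, ddof=1))}"
    return f"{_round2(np.mean(x))} ± NA"


def _fmt_skewed(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{_round2(med)} ({_round2(q1)}–{_round2(q3)})"


def _clean(frame: pd.DataFrame, var: str, mask: np.ndarray) -> np.ndarray:
    x = pd.to_numeric(frame.loc[mask, var], errors="coerce").to_numpy(dtype=float)
    return x[np.isfinite(x)]


def compare_groups(
    frame: pd.DataFrame,
    group_masks: Mapping[str, np.ndarray],
    variables: Sequence[tuple] = tuple(_VARIABLES),
) -> pd.DataFrame:
    """Generic k-group comparison table.

    Two groups use chi-square/Fisher, t, or Wilcoxon per variable kind;
    three or more use chi-square on the k×2 table, one-way ANOVA, or
    Kruskal–Wallis.  An empty stratum flags the row instead of dividing by
    zero.
    """
    names = list(group_masks)
    masks = [np.asarray(group_masks[g], dtype=bool) for g in names]
    rows = []
    for var, kind in variables:
        if var not in frame.columns:
            continue
        row: dict = {"variable": var, "type": kind}
        flagged = any(m.sum() == 0 for m in masks)
        if kind == BINARY:
            col = frame[var].astype(bool).to_numpy()
            for g, m in zip(names, masks):
                num, den = int(col[m].sum()), int(m.sum())
                row[g] = _fmt_binary(num, den) if den else "empty stratum"
                row[f"{g}_num"], row[f"{g}_den"] = num, den
            if not flagged:
                counts = np.array([[int(col[m].sum()), int(m.sum() - col[m].sum())] for m in masks])
                try:
                    if len(masks) == 2:
                        res = chi_square_test(
                            ContingencyTable(
                                counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1]
                            )
                        )
                        row["p_value"], row["test"] = res.p_value, res.method
                    else:
                        stat, p, _, _ = sps.chi2_contingency(counts, correction=False)
                        row["p_value"], row["test"] = float(p), "chi2_k"
                except ValueError:
                    row["p_value"], row["test"] = float("nan"), "degenerate"
        else:
            samples = [_clean(frame, var, m) for m in masks]
            flagged = flagged or any(s.size == 0 for s in samples)
            fmt = _fmt_normal if kind == NORMAL else _fmt_skewed
            for g, s in zip(names, samples):
                row[g] = fmt(s) if s.size else "empty stratum"
            if not flagged:
                if len(samples) == 2:
                    res = t_compare(*samples) if kind == NORMAL else rank_compare(*samples)
                    row["p_value"], row["test"] = res.p_value, res.method
                elif kind == NORMAL:
                    stat, p = sps.f_oneway(*samples)
                    row["p_value"], row["test"] = float(p), "anova"
                else:
                    stat, p = sps.kruskal(*samples)
                    row["p_value"], row["test"] = float(p), "kruskal"
        if flagged:
            row["p_value"], row["test"] = float("nan"), "empty_stratum"
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(
    records: Sequence[PatientRecord],
    assessments: Mapping[str, AKIAssessment],
    rai_results: Mapping[str, RAIResult],
    fluid_summaries: Mapping[str, FluidSummary],
    scr_ratios: Mapping[str, float] | None = None,
) -> CohortSummary:
    """Build the four analysis tables from per-patient components."""
    frame = assemble_analysis_frame(records, assessments, rai_results, fluid_summaries)
    if scr_ratios is not None:
        frame = attach_scr_gt_base(frame, scr_ratios)
    tables = {}
    died = frame["died"].to_numpy(dtype=bool)
    tables["survival"] = compare_groups(
        frame, {"survivors": ~died, "non_survivors": died}
    )
    severe = frame["severe_aki"].to_numpy(dtype=bool)
    tables["aki"] = compare_groups(frame, {"non_akis": ~severe, "akis": severe})
    raip = frame["rai_positive"].to_numpy(dtype=bool)
    tables["rai"] = compare_groups(frame, {"rai_neg": ~raip, "rai_pos": raip})
    groups = {"rai_pos": raip, "fo_pos": frame["fo_positive"].to_numpy(dtype=bool)}
    if "scr_gt_base" in frame.columns:
        groups = {
            "rai_pos": raip,
            "scr_gt_base": frame["scr_gt_base"].to_numpy(dtype=bool),
            "fo_pos": groups["fo_pos"],
        }
    tables["predictors"] = compare_groups(frame, groups)
    return CohortSummary(frame=frame, tables=tables)
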