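"""End-to-end analysis pipeline: read → eligibility → staging → FO → RAI → statistics.

Produces a report bundle on disk: per-patient component tables
(``eligibility.csv``, ``aki_assessments.csv``, ``fluid_summaries.csv``,
``rai_results.csv``), the group-comparison tables under
``summary_tables/``, ROC coordinates per predictor, a machine-readable
``results.json`` and a run log.  Every number in the report is
re-derivable from the emitted intermediate files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .fluid import summarize_fluid
from .kdigo import SCHWARTZ_K, assess, baseline_scr, first_onset_any
from .rai import compute_rai, rai_input_from_record
from .records import PatientRecord, apply_eligibility, read_cohort
from .stats import (
    ContingencyTable,
    auc_binary,
    auc_scores,
    chi_square_test,
    combined_predictor_auc,
    fit_logistic,
    odds_ratio_wald,
    youden_cutoff,
)
from .summary import summarize_cohort

logger = logging.getLogger(__name__)


class InputError(Exception):
    """Invalid or missing input (CLI exit code 1)."""


class ComputationError(Exception):
    """A pipeline stage failed on valid-looking input (CLI exit code 2)."""


@dataclass
class RunConfig:
    cohort_path: str
    timeseries_path: str
    out_dir: str
    use_uo: bool = True  # kdigo.use_uo
    fo_window_h: float = 24.0
    rai_fo_window_h: float = 24.0  # FO window feeding the RAI injury stratum
    rai_window_h: float = 12.0
    schwartz_k: float = SCHWARTZ_K
    seed: Optional[int] = None
    verbosity: str = "info"

    def validate(self) -> None:
        for p in (self.cohort_path, self.timeseries_path):
            if not Path(p).exists():
                raise InputError(f"input file not found: {p}")
        for w in (self.fo_window_h, self.rai_fo_window_h, self.rai_window_h):
            if w <= 0:
                raise InputError("windows must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config_file(path) -> dict:
    """Flat ``dotted.key = value`` configuration text."""
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise InputError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    return values


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (InputError, ComputationError):
                raise
            except FileNotFoundError as exc:
                raise InputError(f"stage {name}: {exc}") from exc
            except ValueError as exc:
                raise ComputationError(f"stage {name}: {exc}") from exc

        return inner

    return wrap


@dataclass
class PipelineResult:
    eligible_records: list
    eligibility: pd.DataFrame
    assessments: dict
    fluid_summaries: dict
    rai_results: dict
    scr_ratios: dict
    summary: object
    stats: dict
    roc_curves: dict = field(default_factory=dict)


def analyze_records(records: Sequence[PatientRecord], config: RunConfig) -> PipelineResult:
    """Run every pipeline stage on in-memory records."""
    # baselines + staging over the 72 h window
    baselines = {}
    assessments = {}
    onset_any = {}
    for rec in records:
        try:
            bl = baseline_scr(rec, k=config.schwartz_k)
        except ValueError as exc:
            raise ComputationError(f"stage baseline: {exc}") from exc
        baselines[rec.patient_id] = bl
        assessments[rec.patient_id] = assess(rec, bl, use_uo=config.use_uo)
        onset_any[rec.patient_id] = first_onset_any(rec, bl, use_uo=config.use_uo)

    decisions = apply_eligibility(records, assessments, onset_any)
    eligibility = pd.DataFrame(
        {
            "patient_id": [d.patient_id for d in decisions],
            "eligible": [d.eligible for d in decisions],
            "exclusion_reason": [d.exclusion_reason.value for d in decisions],
        }
    )
    eligible = [r for r, d in zip(records, decisions) if d.eligible]
    if not eligible:
        raise ComputationError("stage eligibility: no eligible patients")
    logger.info("eligibility: %d of %d patients retained", len(eligible), len(records))

    fluid_summaries = {r.patient_id: summarize_fluid(r, config.fo_window_h) for r in eligible}
    rai_fluid = (
        fluid_summaries
        if config.rai_fo_window_h == config.fo_window_h
        else {r.patient_id: summarize_fluid(r, config.rai_fo_window_h) for r in eligible}
    )
    rai_inputs = {
        r.patient_id: rai_input_from_record(
            r, baselines[r.patient_id], rai_fluid[r.patient_id], config.rai_window_h
        )
        for r in eligible
    }
    rai_results = {pid: compute_rai(inp) for pid, inp in rai_inputs.items()}
    scr_ratios = {pid: inp.scr_ratio for pid, inp in rai_inputs.items()}

    summary = summarize_cohort(eligible, assessments, rai_results, fluid_summaries, scr_ratios)
    stats, roc_curves = _predictive_stats(summary.frame)
    return PipelineResult(
        eligible_records=eligible,
        eligibility=eligibility,
        assessments={r.patient_id: assessments[r.patient_id] for r in eligible},
        fluid_summaries=fluid_summaries,
        rai_results=rai_results,
        scr_ratios=scr_ratios,
        summary=summary,
        stats=stats,
        roc_curves=roc_curves,
    )


def _predictive_stats(frame: pd.DataFrame) -> tuple[dict, dict]:
    """Odds ratios, AUCs, the lactate cutoff and the combined model."""
    outcome = frame["severe_aki"].to_numpy(dtype=bool)
    stats: dict = {"n": int(len(frame))}
    curves: dict = {}
    for name, col in (
        ("rai_positive", "rai_positive"),
        ("scr_gt_base", "scr_gt_base"),
        ("fo_positive", "fo_positive"),
    ):
        if col not in frame.columns:
            continue
        flags = frame[col].to_numpy(dtype=bool)
        table = ContingencyTable.from_flags(flags, outcome)
        entry: dict = {"table": [table.a, table.b, table.c, table.d]}
        try:
            orr = odds_ratio_wald(table)
            entry["odds_ratio"] = {
                "or": orr.or_point,
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
                "p_value": orr.p_value,
            }
        except ValueError as exc:
            entry["odds_ratio"] = {"error": str(exc)}
        try:
            chi = chi_square_test(table)
            entry["chi_square"] = {
                "statistic": chi.statistic,
                "p_value": chi.p_value,
                "method": chi.method,
            }
            roc = auc_binary(table)
            entry["auc"] = {"auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high}
            curves[name] = roc.curve_points
        except ValueError as exc:
            entry.setdefault("auc", {"error": str(exc)})
        stats[name] = entry

    lact = frame["lactate_mmol_per_L"].to_numpy(dtype=float)
    if outcome.any() and (~outcome).any():
        roc = auc_scores(lact, outcome.astype(int))
        cut = youden_cutoff(lact, outcome.astype(int))
        stats["lactate"] = {
            "auc": {"auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high},
            "youden_cutoff": cut.threshold,
            "sensitivity": cut.sensitivity,
            "specificity": cut.specificity,
        }
        curves["lactate"] = roc.curve_points
        try:
            roc_c, fit_c = combined_predictor_auc(
                frame["rai_positive"].to_numpy(dtype=bool), lact, outcome.astype(int), return_fit=True
            )
            stats["combined_rai_lactate"] = {
                "auc": {"auc": roc_c.auc, "ci_low": roc_c.ci_low, "ci_high": roc_c.ci_high},
                "coefficients": dict(zip(fit_c.names, fit_c.params.tolist())),
            }
            curves["combined_rai_lactate"] = roc_c.curve_points
        except RuntimeError as exc:
            stats["combined_rai_lactate"] = {"error": str(exc)}

        # pre-specified multivariable model: early RAI+, early VS, serum lactate
        X = np.column_stack(
            [
                frame["rai_positive"].to_numpy(dtype=float),
                frame["vs"].to_numpy(dtype=float),
                lact,
            ]
        )
        fit = fit_logistic(outcome.astype(int), X, names=["rai_positive", "vs", "lactate"])
        stats["multivariable"] = {
            "converged": fit.converged,
            "diagnostic": fit.diagnostic,
            "odds_ratios": {
                name: {
                    "or": float(orv),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "p_value": float(p),
                }
                for name, orv, lo, hi, p in zip(
                    fit.names, fit.odds_ratios, fit.or_ci_low, fit.or_ci_high, fit.p_values
                )
            },
        }
    return stats, curves


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline from CSV inputs and write the report bundle."""
    config.validate()
    read = _stage("read")(read_cohort)
    records = read(config.cohort_path, config.timeseries_path)
    result = analyze_records(records, config)
    write_bundle(result, config)
    return result


def write_bundle(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.eligibility.to_csv(out / "eligibility.csv", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": a.patient_id,
                "stage_by_72h": a.stage_by_72h,
                "severe_aki": a.severe_aki,
                "first_aki_onset_h": a.first_aki_onset_h,
                "first_severe_onset_h": a.first_severe_onset_h,
            }
            for a in result.assessments.values()
        ]
    ).to_csv(out / "aki_assessments.csv", index=False)
    pd.DataFrame(
        [
            {"patient_id": f.patient_id, "fo_percent": f.fo_percent, "fo_positive": f.fo_positive}
            for f in result.fluid_summaries.values()
        ]
    ).to_csv(out / "fluid_summaries.csv", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "risk_score": r.risk_score,
                "injury_score": r.injury_score,
                "rai": r.rai,
                "rai_positive": r.rai_positive,
            }
            for r in result.rai_results.values()
        ]
    ).to_csv(out / "rai_results.csv", index=False)

    tdir = out / "summary_tables"
    tdir.mkdir(exist_ok=True)
    for name, table in result.summary.tables.items():
        table.to_csv(tdir / f"{name}.csv", index=False)
    result.summary.frame.to_csv(out / "analysis_frame.csv", index=False)

    for name, pts in result.roc_curves.items():
        pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(out / f"roc_{name}.csv", index=False)

    with open(out / "results.json", "w") as fh:
        json.dump(result.stats, fh, indent=2, default=float)

    with open(out / "run.log", "w") as fh:
        fh.write(f"renal-angina {__version__}\n")
        fh.write(f"python {sys.version.split()[0]}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"config hash: {config.config_hash()}\n")
        fh.write(f"config: {json.dumps(asdict(config), default=str)}\n")
        fh.write(
            f"patients: {len(result.eligibility)} read, "
            f"{len(result.eligible_records)} eligible\n"
        )
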