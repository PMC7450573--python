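"""Synthetic septic-shock PICU cohorts.

Two generation layers share one configuration:

* **indicator level** — per-patient binary indicators and covariates drawn
  directly from their conditional laws given severe-AKI status.  This is
  the layer the statistics are exercised on.
* **trajectory level** — raw records (covariates plus creatinine, urine and
  fluid time series) constructed so that running the full pipeline
  (baseline → staging → fluid overload → RAI) reproduces the indicator
  laws, and optionally including the four exclusion archetypes
  (short stay / known kidney disease / late-onset AKI / early severe AKI)
  for eligibility testing.

Defaults encode a 66-patient cohort with severe-AKI prevalence 36/66 and
the conditional indicator frequencies and biomarker locations of that
cohort (RAI+ 83.33 % / 26.67 % given severe / non-severe, creatinine
elevation 77.78 % / 36.67 %, fluid overload 25 % / 6.67 %, mechanical
ventilation 77.78 % / 30 %, vasoactive support 80.56 % / 30 %, death
69.44 % / 6.67 %; lactate log-normal with medians ≈ 4.0 vs 2.8 mmol/L).
Indicators are drawn conditionally independent given the severe-AKI label
— the maximum-entropy choice when only margins are known — with an
optional Gaussian-copula correlation knob between RAI+ and creatinine
elevation, since creatinine enters both definitions.

Skewed covariates are modelled log-normal with parameters solved from the
median and IQR; the heavy asymmetry of some printed IQRs (platelets in the
non-severe group) cannot be matched exactly by a two-parameter law, so the
median and the quartile *ratio* are honoured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .records import PatientRecord, Series

Z75 = 0.6744897501960817  # 75th normal percentile

DEFAULT_SEED = 20160101


def lognormal_from_quartiles(median: float, q1: float, q3: float) -> Tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and quartile ratio."""
    if not (0 < q1 <= median <= q3):
        raise ValueError("need 0 < q1 <= median <= q3")
    return math.log(median), math.log(q3 / q1) / (2 * Z75)


@dataclass(frozen=True)
class Conditional:
    """P(indicator | severe AKI) and P(indicator | no severe AKI)."""

    given_severe: float
    given_nonsevere: float

    def __post_init__(self) -> None:
        for p in (self.given_severe, self.given_nonsevere):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")

    def p(self, severe: bool) -> float:
        return self.given_severe if severe else self.given_nonsevere


@dataclass
class GeneratorConfig:
    """Indicator-level cohort law."""

    n_patients: int = 66
    seed: int = DEFAULT_SEED
    prevalence_severe_aki: float = 36 / 66
    rai_positive: Conditional = field(default_factory=lambda: Conditional(30 / 36, 8 / 30))
    scr_gt_base: Conditional = field(default_factory=lambda: Conditional(28 / 36, 11 / 30))
    fo_positive: Conditional = field(default_factory=lambda: Conditional(9 / 36, 2 / 30))
    mv: Conditional = field(default_factory=lambda: Conditional(28 / 36, 9 / 30))
    vs: Conditional = field(default_factory=lambda: Conditional(29 / 36, 9 / 30))
    rrt: Conditional = field(default_factory=lambda: Conditional(13 / 36, 3 / 30))
    died: Conditional = field(default_factory=lambda: Conditional(25 / 36, 2 / 30))
    male: Conditional = field(default_factory=lambda: Conditional(24 / 36, 20 / 30))
    underlying_disease: Conditional = field(default_factory=lambda: Conditional(26 / 36, 15 / 30))
    transplant: Conditional = field(default_factory=lambda: Conditional(0.04, 0.04))
    # log-normal (mu, sigma) per group, severe first
    lactate_severe: Tuple[float, float] = lognormal_from_quartiles(4.00, 2.80, 9.10)
    lactate_nonsevere: Tuple[float, float] = lognormal_from_quartiles(2.80, 1.65, 3.87)
    aptt_severe: Tuple[float, float] = lognormal_from_quartiles(55.85, 48.15, 76.17)
    aptt_nonsevere: Tuple[float, float] = lognormal_from_quartiles(46.20, 37.05, 51.77)
    platelet_severe: Tuple[float, float] = lognormal_from_quartiles(32.0, 15.0, 83.25)
    platelet_nonsevere: Tuple[float, float] = lognormal_from_quartiles(225.5, 30.75, 316.0)
    prism3_severe: Tuple[float, float] = lognormal_from_quartiles(14.0, 12.0, 18.0)
    prism3_nonsevere: Tuple[float, float] = lognormal_from_quartiles(6.0, 3.0, 12.0)
    pelod2_severe: Tuple[float, float] = lognormal_from_quartiles(7.0, 4.0, 9.75)
    pelod2_nonsevere: Tuple[float, float] = lognormal_from_quartiles(3.0, 2.0, 5.25)
    # normal (mean, sd) per group
    albumin_severe: Tuple[float, float] = (30.38, 7.35)
    albumin_nonsevere: Tuple[float, float] = (33.92, 6.09)
    age_months_dist: Tuple[float, float] = lognormal_from_quartiles(58.0, 8.5, 131.75)
    # Gaussian-copula correlation between the RAI+ and SCr>base draws
    rai_scr_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need n_patients >= 2")
        if not 0.0 <= self.prevalence_severe_aki <= 1.0:
            raise ValueError("prevalence must be a probability")
        if not -1.0 < self.rai_scr_correlation < 1.0:
            raise ValueError("correlation must lie in (-1, 1)")


@dataclass
class TrajectoryConfig:
    """Raw time-series layer.

    Within-72-h severe onsets are drawn after the 12 h eligibility horizon;
    non-severe patients on renal replacement therapy (a fluid-overload
    indication) start it after 72 h so the stage-3 RRT rule does not
    reclassify them.  Stage targets follow the cohort stage split: among
    severe patients 31/36 reach stage 3, and among the non-severe 17/30
    reach stage 1.
    """

    p_stage3_given_severe: float = 31 / 36
    p_stage1_given_nonsevere: float = 17 / 30
    p_measured_baseline: float = 0.5
    severe_onset_range_h: Tuple[float, float] = (14.0, 66.0)
    p_oliguria_given_severe: float = 0.3
    oliguria_rate_range: Tuple[float, float] = (0.32, 0.45)  # mL/kg/h; stage <= 2 by urine
    urine_rate_range: Tuple[float, float] = (1.0, 2.5)  # mL/kg/h
    fo_nonpos_mean_sd: Tuple[float, float] = (2.0, 3.0)  # % of body weight
    fo_pos_range: Tuple[float, float] = (10.5, 22.0)
    scr_grid_h: Tuple[float, ...] = (2.0, 6.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0)


# ---------------------------------------------------------------------------
# indicator level


def _draw_correlated_pair(rng, p1: float, p2: float, rho: float) -> Tuple[bool, bool]:
    from scipy.stats import norm

    if rho == 0.0:
        return bool(rng.random() < p1), bool(rng.random() < p2)
    z1 = rng.standard_normal()
    z2 = rho * z1 + math.sqrt(1 - rho * rho) * rng.standard_normal()
    return bool(norm.cdf(z1) < p1), bool(norm.cdf(z2) < p2)


def generate_indicator_cohort(
    config: Optional[GeneratorConfig] = None,
    n: Optional[int] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Draw an indicator-level cohort table; reproducible for a fixed seed."""
    cfg = config or GeneratorConfig()
    n = cfg.n_patients if n is None else n
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    width = max(4, len(str(n)))
    for i in range(n):
        severe = bool(rng.random() < cfg.prevalence_severe_aki)
        raip, scrgt = _draw_correlated_pair(
            rng, cfg.rai_positive.p(severe), cfg.scr_gt_base.p(severe), cfg.rai_scr_correlation
        )
        lac_mu, lac_sig = cfg.lactate_severe if severe else cfg.lactate_nonsevere
        alb_m, alb_s = cfg.albumin_severe if severe else cfg.albumin_nonsevere
        aptt_mu, aptt_sig = cfg.aptt_severe if severe else cfg.aptt_nonsevere
        plt_mu, plt_sig = cfg.platelet_severe if severe else cfg.platelet_nonsevere
        prism_mu, prism_sig = cfg.prism3_severe if severe else cfg.prism3_nonsevere
        pelod_mu, pelod_sig = cfg.pelod2_severe if severe else cfg.pelod2_nonsevere
        age_mu, age_sig = cfg.age_months_dist
        rows.append(
            {
                "patient_id": f"S{i + 1:0{width}d}",
                "severe_aki": severe,
                "rai_positive": raip,
                "scr_gt_base": scrgt,
                "fo_positive": bool(rng.random() < cfg.fo_positive.p(severe)),
                "mv": bool(rng.random() < cfg.mv.p(severe)),
                "vs": bool(rng.random() < cfg.vs.p(severe)),
                "rrt": bool(rng.random() < cfg.rrt.p(severe)),
                "died": bool(rng.random() < cfg.died.p(severe)),
                "male": bool(rng.random() < cfg.male.p(severe)),
                "underlying_disease": bool(rng.random() < cfg.underlying_disease.p(severe)),
                "transplant": bool(rng.random() < cfg.transplant.p(severe)),
                "age_months": float(np.clip(rng.lognormal(age_mu, age_sig), 1.0, 192.0)),
                "lactate_mmol_per_L": float(rng.lognormal(lac_mu, lac_sig)),
                "albumin_g_per_L": float(max(rng.normal(alb_m, alb_s), 5.0)),
                "aptt_s": float(rng.lognormal(aptt_mu, aptt_sig)),
                "platelet_1e9_per_L": float(rng.lognormal(plt_mu, plt_sig)),
                "prism3": float(round(rng.lognormal(prism_mu, prism_sig))),
                "pelod2": float(round(rng.lognormal(pelod_mu, pelod_sig))),
            }
        )
    return pd.DataFrame(rows)


def generate_logistic_cohort(
    n: int,
    seed: int,
    or_rai: float = 10.0,
    or_vs: float = 9.0,
    or_lactate_per_unit: float = 1.24,
    intercept: float = -3.6,
    p_rai: float = 38 / 66,
    p_vs: float = 38 / 66,
    lactate_dist: Tuple[float, float] = lognormal_from_quartiles(3.3, 2.0, 6.0),
) -> pd.DataFrame:
    """Cohort drawn from an explicit logistic outcome model.

    Used for parameter-recovery checks: the outcome is Bernoulli with
    logit = intercept + ln(or_rai)·RAI+ + ln(or_vs)·VS + ln(or_lactate)·lactate.
    """
    rng = np.random.default_rng(seed)
    raip = rng.random(n) < p_rai
    vs = rng.random(n) < p_vs
    lact = rng.lognormal(*lactate_dist, size=n)
    logit = (
        intercept
        + math.log(or_rai) * raip
        + math.log(or_vs) * vs
        + math.log(or_lactate_per_unit) * lact
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    outcome = rng.random(n) < p
    return pd.DataFrame(
        {
            "rai_positive": raip,
            "vs": vs,
            "lactate_mmol_per_L": lact,
            "severe_aki": outcome,
        }
    )


# ---------------------------------------------------------------------------
# trajectory level

_SCHWARTZ_K = 0.413
_MGDL_TO_UMOL = 88.4
_BASE_TIME = pd.Timestamp("2016-01-01T08:00:00")


def _anthropometry(rng, age_months: float) -> Tuple[float, float]:
    """(height_cm, weight_kg) from age with biological noise."""
    years = age_months / 12.0
    if age_months < 12:
        height = 52.0 + 2.0 * age_months
        weight = 3.8 + 0.55 * age_months
    else:
        height = min(75.0 + 6.2 * years, 172.0)
        weight = min(8.0 + 2.2 * years, 55.0)
    height = float(np.clip(height * math.exp(rng.normal(0.0, 0.04)), 45.0, 180.0))
    weight = float(np.clip(weight * math.exp(rng.normal(0.0, 0.12)), 2.5, 80.0))
    return height, weight


def _interp_ratio(grid: np.ndarray, knots_t, knots_r) -> np.ndarray:
    return np.interp(grid, knots_t, knots_r)


def _build_series(
    rng,
    cfg: TrajectoryConfig,
    row: dict,
    weight: float,
    baseline: float,
) -> Tuple[dict, Optional[float], Optional[float], float]:
    """Create the four series for one eligible patient.

    Returns (series dict, rrt_offset_h, severe_onset_h, fo_percent_24h).
    """
    severe = row["severe_aki"]
    scr_gt = row["scr_gt_base"]

    # --- creatinine ratio trajectory ------------------------------------
    onset = None
    stage3 = False
    if severe:
        stage3 = rng.random() < cfg.p_stage3_given_severe
        onset = float(rng.uniform(*cfg.severe_onset_range_h))
        peak = float(rng.uniform(3.0, 4.2)) if stage3 else float(rng.uniform(2.1, 2.9))
        r12 = float(rng.uniform(1.2, 1.9)) if scr_gt else float(rng.uniform(0.78, 0.98))
        knots_t = [0.0, 12.0, onset, min(onset + 10.0, 72.0), 72.0]
        knots_r = [0.92 * r12, r12, 2.0, peak, peak]
    else:
        # non-severe patients on RRT (fluid-overload indication, started
        # after 72 h) are routed through the stage-1 arm so their first AKI
        # onset falls inside the window and late RRT cannot read as
        # late-onset AKI
        stage1 = (rng.random() < cfg.p_stage1_given_nonsevere) or row["rrt"]
        if stage1:
            r12 = float(rng.uniform(1.05, 1.45)) if scr_gt else float(rng.uniform(0.78, 0.98))
            peak = float(rng.uniform(1.5, 1.9))
            tpk = float(rng.uniform(16.0, 60.0))
            knots_t = [0.0, 12.0, tpk, 72.0]
            knots_r = [0.92 * r12, r12, peak, max(peak - 0.2, r12)]
        else:
            # stage 0: stay below every criterion, including the 26.5 µmol/L
            # 48 h absolute-rise rule
            cap = min(1.45, 1.0 + 24.0 / baseline)
            if scr_gt:
                r12 = float(rng.uniform(1.02, cap))
                r0 = r12 - min(0.15, 20.0 / baseline)
            else:
                r12 = float(rng.uniform(0.78, 0.98))
                r0 = r12
            knots_t = [0.0, 12.0, 72.0]
            knots_r = [r0, r12, max(r12 - 0.1, 0.5)]
    # measure on the regular grid plus the trajectory knots, so band
    # crossings appear in the recorded series at their exact times
    grid = np.unique(np.r_[np.asarray(cfg.scr_grid_h), np.clip(knots_t, 0.0, 72.0)])
    grid = grid[grid > 0.0]
    ratios = _interp_ratio(grid, knots_t, knots_r)
    scr_values = np.round(ratios * baseline, 1)

    # --- renal replacement therapy --------------------------------------
    rrt_offset = None
    if row["rrt"]:
        if stage3:
            rrt_offset = float(rng.uniform(onset, 72.0))
        else:
            # RRT within the window implies stage 3, so patients not bound
            # for stage 3 start it after 72 h (e.g. for fluid overload)
            rrt_offset = float(rng.uniform(76.0, 120.0))

    # --- urine -----------------------------------------------------------
    rate = float(rng.uniform(*cfg.urine_rate_range))
    bins = np.arange(6.0, 72.1, 6.0)
    rates = np.full(bins.shape, rate)
    if severe and rng.random() < cfg.p_oliguria_given_severe:
        # oliguric but above the 0.3 mL/kg/h stage-3 line, so the urine
        # route cannot override the configured stage split
        olig_rate = float(rng.uniform(*cfg.oliguria_rate_range))
        rates[bins > onset] = olig_rate
    urine = np.round(rates * weight * 6.0, 1)

    # --- fluids (first 24 h, 6 h bins) -----------------------------------
    if row["fo_positive"]:
        fo = float(rng.uniform(*cfg.fo_pos_range))
    else:
        fo = float(min(rng.normal(*cfg.fo_nonpos_mean_sd), 9.5))
    net_ml = fo / 100.0 * weight * 1000.0
    out_total = weight * float(rng.uniform(1.0, 2.0)) * 24.0
    if out_total + net_ml < 0:
        out_total = -net_ml + 5.0 * weight
    in_total = out_total + net_ml
    fbins = np.array([6.0, 12.0, 18.0, 24.0])
    series = {
        "scr_umol_per_L": Series(grid.copy(), scr_values),
        "urine_mL": Series(bins.copy(), urine),
        "fluid_in_mL": Series(fbins.copy(), np.round(np.full(4, in_total / 4.0), 1)),
        "fluid_out_mL": Series(fbins.copy(), np.round(np.full(4, out_total / 4.0), 1)),
    }
    return series, rrt_offset, onset, fo


def _record_from_row(
    rng,
    cfg: TrajectoryConfig,
    row: dict,
    index: int,
    pid: str,
) -> PatientRecord:
    height, weight = _anthropometry(rng, row["age_months"])
    schwartz = _SCHWARTZ_K * height / 120.0 * _MGDL_TO_UMOL
    measured = None
    if rng.random() < cfg.p_measured_baseline:
        measured = round(schwartz * math.exp(rng.normal(0.0, 0.08)), 1)
    baseline = measured if measured is not None else schwartz

    series, rrt_offset, _, _ = _build_series(rng, cfg, row, weight, baseline)

    admission = _BASE_TIME + pd.Timedelta(hours=31 * index)
    los_days = float(rng.uniform(2.5, 20.0)) if row["died"] else float(rng.uniform(3.0, 30.0))
    if rrt_offset is not None:
        los_days = max(los_days, (rrt_offset + 24.0) / 24.0)
    mv_t = admission + pd.Timedelta(hours=round(rng.uniform(0.5, 10.0), 1)) if row["mv"] else None
    vs_t = admission + pd.Timedelta(hours=round(rng.uniform(0.5, 10.0), 1)) if row["vs"] else None
    rrt_t = admission + pd.Timedelta(hours=round(rrt_offset, 1)) if rrt_offset is not None else None

    return PatientRecord(
        patient_id=pid,
        age_months=round(row["age_months"], 1),
        sex="male" if row["male"] else "female",
        admission_weight_kg=round(weight, 1),
        admission_time=admission,
        discharge_or_death_time=admission + pd.Timedelta(hours=round(los_days * 24.0, 1)),
        known_kidney_disease=row.get("known_kidney_disease", False),
        transplant=row["transplant"],
        underlying_disease=row["underlying_disease"],
        lactate_mmol_per_L=round(row["lactate_mmol_per_L"], 2),
        died=row["died"],
        height_cm=round(height, 1),
        baseline_scr_umol_per_L=measured,
        mv_start_time=mv_t,
        vs_start_time=vs_t,
        rrt_start_time=rrt_t,
        albumin_g_per_L=round(row["albumin_g_per_L"], 2),
        aptt_s=round(row["aptt_s"], 2),
        platelet_1e9_per_L=round(row["platelet_1e9_per_L"], 1),
        prism3=row["prism3"],
        pelod2=row["pelod2"],
        series=series,
    )


def _benign_overrides(rec: PatientRecord, baseline_ratio: float = 0.9) -> None:
    """Flatten a record's creatinine and urine so no AKI criterion fires."""
    base = rec.baseline_scr_umol_per_L or (_SCHWARTZ_K * rec.height_cm / 120.0 * _MGDL_TO_UMOL)
    grid = rec.scr_series.times
    rec.series["scr_umol_per_L"] = Series(
        grid, np.round(np.full(grid.shape, baseline_ratio * base), 1)
    )
    bins = np.arange(6.0, 72.1, 6.0)
    rec.series["urine_mL"] = Series(
        bins, np.round(np.full(bins.shape, 1.5 * rec.admission_weight_kg * 6.0), 1)
    )
    rec.rrt_start_time = None


def generate_trajectory_cohort(
    config: Optional[GeneratorConfig] = None,
    trajectory_config: Optional[TrajectoryConfig] = None,
    n: Optional[int] = None,
    seed: Optional[int] = None,
    exclusion_counts: Tuple[int, int, int, int] = (3, 5, 4, 6),
) -> list:
    """Generate raw patient records for the full pipeline.

    Returns ``n`` eligible-by-construction records followed by the four
    exclusion archetypes in ``exclusion_counts`` order (short stay, known
    kidney disease, AKI onset after 72 h, severe AKI within 12 h).  Same
    seed, same records.
    """
    cfg = config or GeneratorConfig()
    tcfg = trajectory_config or TrajectoryConfig()
    n = cfg.n_patients if n is None else n
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    indicators = generate_indicator_cohort(cfg, n=n, seed=int(rng.integers(2**31)))
    records = []
    width = max(4, len(str(n + sum(exclusion_counts))))
    for i, row in enumerate(indicators.to_dict("records")):
        records.append(_record_from_row(rng, tcfg, row, i, f"P{i + 1:0{width}d}"))

    # exclusion archetypes, appended after the eligible block
    n_short, n_kidney, n_late, n_early = exclusion_counts
    extra_n = n_short + n_kidney + n_late + n_early
    extra = generate_indicator_cohort(cfg, n=extra_n, seed=int(rng.integers(2**31)))
    kinds = (
        ["short_stay"] * n_short
        + ["kidney_disease"] * n_kidney
        + ["late_onset"] * n_late
        + ["early_severe"] * n_early
    )
    for j, (row, kind) in enumerate(zip(extra.to_dict("records"), kinds)):
        idx = n + j
        rec = _record_from_row(rng, tcfg, row, idx, f"P{idx + 1:0{width}d}")
        base = rec.baseline_scr_umol_per_L or (
            _SCHWARTZ_K * rec.height_cm / 120.0 * _MGDL_TO_UMOL
        )
        if kind == "short_stay":
            _benign_overrides(rec)
            rec.discharge_or_death_time = rec.admission_time + pd.Timedelta(hours=30)
            grid = rec.scr_series.times
            keep = grid <= 30.0
            rec.series["scr_umol_per_L"] = Series(
                grid[keep], rec.scr_series.values[keep]
            )
        elif kind == "kidney_disease":
            _benign_overrides(rec)
            rec.known_kidney_disease = True
        elif kind == "late_onset":
            _benign_overrides(rec)
            grid = np.r_[rec.scr_series.times, 76.0, 80.0]
            vals = np.r_[rec.scr_series.values, round(1.6 * base, 1), round(1.7 * base, 1)]
            rec.series["scr_umol_per_L"] = Series(grid, vals)
        elif kind == "early_severe":
            _benign_overrides(rec)
            grid = rec.scr_series.times
            vals = rec.scr_series.values.copy()
            vals[grid >= 6.0] = round(2.3 * base, 1)
            rec.series["scr_umol_per_L"] = Series(grid, vals)
            rec.discharge_or_death_time = rec.admission_time + pd.Timedelta(hours=200)
        records.append(rec)
    return records
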