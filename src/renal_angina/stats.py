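"""Predictive-performance statistics for binary and composite predictors.

2×2 odds ratios with Wald confidence intervals, Pearson chi-square with an
automatic Fisher fallback, rank/t group comparisons, logistic regression by
Newton–Raphson IRLS, ROC/AUC by the Mann–Whitney construction with
Hanley–McNeil confidence intervals, and the Youden-index optimal cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 exposure × outcome counts.

    ``a`` exposed with outcome, ``b`` exposed without, ``c`` unexposed with
    outcome, ``d`` unexposed without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @classmethod
    def from_flags(cls, exposure: Sequence[bool], outcome: Sequence[bool]) -> "ContingencyTable":
        e = np.asarray(exposure, dtype=bool)
        o = np.asarray(outcome, dtype=bool)
        if e.shape != o.shape:
            raise ValueError("exposure and outcome must be aligned")
        return cls(
            a=int(np.sum(e & o)),
            b=int(np.sum(e & ~o)),
            c=int(np.sum(~e & o)),
            d=int(np.sum(~e & ~o)),
        )

    def transpose_exposure(self) -> "ContingencyTable":
        """Swap exposed and unexposed rows."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class OddsRatioResult:
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def odds_ratio_wald(table: ContingencyTable, haldane_correction: bool = False) -> OddsRatioResult:
    """Sample odds ratio with 95% Wald CI on the log scale.

    OR = ad/bc; CI = exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)); the p-value comes
    from the Wald z statistic.  Zero cells are an error unless the Haldane
    +0.5 correction is enabled.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    for name, v in zip("abcd", (a, b, c, d)):
        if v == 0:
            if not haldane_correction:
                raise ValueError(f"zero cell '{name}' (enable the Haldane correction)")
    if haldane_correction and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_point)
    lo, hi = math.exp(log_or - Z_95 * se), math.exp(log_or + Z_95 * se)
    z = log_or / se
    p = 2 * sps.norm.sf(abs(z))
    return OddsRatioResult(or_point, lo, hi, float(p))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    method: str  # "pearson" or "fisher"


def chi_square_test(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) on a 2×2.

    Falls back to Fisher's exact test when any expected count is below 5;
    the result records which test was used.  A degenerate margin (an empty
    row or column) is an error.
    """
    arr = table.as_array
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate margin: empty row or column")
    expected = sps.contingency.expected_freq(arr)
    if np.any(expected < 5):
        _, p = sps.fisher_exact(arr, alternative="two-sided")
        return ChiSquareResult(float("nan"), float(p), "fisher")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return ChiSquareResult(float(stat), float(p), "pearson")


@dataclass(frozen=True)
class GroupCompareResult:
    statistic: float
    p_value: float
    method: str  # "wilcoxon" or "t"


def rank_compare(values_group0: Sequence[float], values_group1: Sequence[float]) -> GroupCompareResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) with midrank ties and the
    normal approximation."""
    g0 = np.asarray(values_group0, dtype=float)
    g1 = np.asarray(values_group1, dtype=float)
    if g0.size == 0 or g1.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(g0 == g0[0]) and np.all(g1 == g0[0]):
        logger.warning("all values identical across both groups; p = 1")
        return GroupCompareResult(float(g0.size * g1.size / 2), 1.0, "wilcoxon")
    res = sps.mannwhitneyu(g0, g1, alternative="two-sided", method="asymptotic")
    return GroupCompareResult(float(res.statistic), float(res.pvalue), "wilcoxon")


def t_compare(values_group0: Sequence[float], values_group1: Sequence[float]) -> GroupCompareResult:
    """Two-sided Student's t for normally distributed covariates."""
    g0 = np.asarray(values_group0, dtype=float)
    g1 = np.asarray(values_group1, dtype=float)
    if g0.size == 0 or g1.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(np.concatenate([g0, g1]) == g0[0]):
        logger.warning("all values identical across both groups; p = 1")
        return GroupCompareResult(0.0, 1.0, "t")
    stat, p = sps.ttest_ind(g0, g1)
    return GroupCompareResult(float(stat), float(p), "t")


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``params`` includes the intercept first when one was added; odds ratios
    are the exponentiated coefficients with 95% Wald intervals from the
    inverse observed information.
    """

    names: list
    params: np.ndarray
    se: np.ndarray
    odds_ratios: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_iterations: int
    diagnostic: str = ""
    llf: float = field(default=float("nan"))

    def linear_predictor(self, X: np.ndarray, add_intercept: bool = True) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if add_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X @ self.params


def fit_logistic(
    outcome: Sequence[int],
    design_matrix,
    names: Optional[Sequence[str]] = None,
    add_intercept: bool = True,
    max_iterations: int = 50,
    score_tol: float = 1e-8,
    coef_tol: float = 1e-10,
) -> LogisticFit:
    """Logistic regression by Newton–Raphson iteratively reweighted least squares.

    Convergence when the maximum absolute score drops below ``score_tol`` or
    the coefficient change below ``coef_tol``, within ``max_iterations``.
    Non-convergence or (quasi-)separation yields a fit flagged
    ``converged=False`` with a diagnostic, and a logged warning — never a
    silent result.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")
    X = np.asarray(design_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + names
    if len(y) != len(X):
        raise ValueError("outcome and design matrix must be aligned")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design matrix has perfectly collinear columns")

    beta = np.zeros(X.shape[1])
    converged = False
    diagnostic = ""
    it = 0
    for it in range(1, max_iterations + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            diagnostic = "singular information matrix (separation or collinearity)"
            break
        beta = beta + step
        if np.max(np.abs(step)) < coef_tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e3:
            diagnostic = "diverging coefficients (likely complete separation)"
            break
    if not converged and not diagnostic:
        diagnostic = f"no convergence in {max_iterations} iterations"
    if converged and np.max(np.abs(beta)) > 15.0:
        # the score equations can be satisfied on separated data as the
        # likelihood plateaus; enormous coefficients give it away
        converged = False
        diagnostic = "separation: coefficient magnitudes diverged"
    if not converged:
        logger.warning("logistic fit flagged: %s", diagnostic)

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1.0 - p), 1e-300, None)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    with np.errstate(over="ignore"):
        ors = np.exp(beta)
        lo = np.exp(beta - Z_95 * se)
        hi = np.exp(beta + Z_95 * se)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2 * sps.norm.sf(np.abs(z))
    eps = 1e-12
    llf = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return LogisticFit(
        names=names,
        params=beta,
        se=se,
        odds_ratios=ors,
        or_ci_low=lo,
        or_ci_high=hi,
        p_values=pvals,
        converged=converged,
        n_iterations=it,
        diagnostic=diagnostic,
        llf=llf,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    curve_points: tuple  # ordered (1-specificity, sensitivity) pairs

    def __post_init__(self) -> None:
        pts = self.curve_points
        if pts[0] != (0.0, 0.0) or pts[-1] != (1.0, 1.0):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        if any(np.diff(xs) < -1e-12) or any(np.diff(ys) < -1e-12):
            raise ValueError("ROC coordinates must be non-decreasing")


def _hanley_mcneil_ci(auc: float, n_cases: int, n_controls: int) -> tuple[float, float]:
    """95% CI from the Hanley–McNeil (1982) variance approximation."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_cases - 1) * (q1 - auc * auc)
        + (n_controls - 1) * (q2 - auc * auc)
    ) / (n_cases * n_controls)
    se = math.sqrt(max(var, 0.0))
    return max(0.0, auc - Z_95 * se), min(1.0, auc + Z_95 * se)


def auc_binary(table: ContingencyTable) -> ROCResult:
    """ROC of a binary test: a single interior vertex at (1−spec, sens).

    AUC = (sensitivity + specificity)/2 with sensitivity a/(a+c) and
    specificity d/(b+d).
    """
    if table.a + table.c == 0 or table.b + table.d == 0:
        raise ValueError("zero outcome margin")
    sens = table.a / (table.a + table.c)
    spec = table.d / (table.b + table.d)
    auc = (sens + spec) / 2.0
    lo, hi = _hanley_mcneil_ci(auc, table.a + table.c, table.b + table.d)
    return ROCResult(auc, lo, hi, ((0.0, 0.0), (1.0 - spec, sens), (1.0, 1.0)))


def auc_scores(scores: Sequence[float], outcomes: Sequence[int]) -> ROCResult:
    """ROC/AUC of a continuous score by the Mann–Whitney construction.

    Ties between a case and a control count one half.  The curve sweeps the
    unique observed thresholds (test positive when score ≥ threshold); the
    CI uses the Hanley–McNeil variance.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must be aligned")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcomes must be binary 0/1")
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one case and one control")
    if np.all(s == s[0]):
        logger.warning("constant scores; AUC = 0.5")
        lo, hi = _hanley_mcneil_ci(0.5, n1, n0)
        return ROCResult(0.5, lo, hi, ((0.0, 0.0), (1.0, 1.0)))
    ranks = sps.rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # curve: thresholds descending over unique score values
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    last = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    pts = [(0.0, 0.0)] + [(fps[i] / n0, tps[i] / n1) for i in last]
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    lo, hi = _hanley_mcneil_ci(float(auc), n1, n0)
    return ROCResult(float(auc), lo, hi, tuple(pts))


def combined_predictor_auc(
    rai_positive_flags: Sequence[bool],
    lactate_values: Sequence[float],
    outcomes: Sequence[int],
    return_fit: bool = False,
):
    """AUC of the combined RAI+ & serum-lactate logistic score.

    Fits outcome ~ RAI+ + lactate, scores patients by the fitted linear
    predictor, and evaluates the ROC of that score.
    """
    flags = np.asarray(rai_positive_flags, dtype=float)
    lact = np.asarray(lactate_values, dtype=float)
    X = np.column_stack([flags, lact])
    names = ["rai_positive", "lactate"]
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    if not keep:
        raise ValueError("both predictors are constant")
    if len(keep) < X.shape[1]:
        logger.warning("constant predictor dropped from the combined model")
    Xk = X[:, keep]
    fit = fit_logistic(outcomes, Xk, names=[names[j] for j in keep])
    if not fit.converged:
        raise RuntimeError(f"combined-model logistic fit failed: {fit.diagnostic}")
    roc = auc_scores(fit.linear_predictor(Xk), outcomes)
    return (roc, fit) if return_fit else roc


@dataclass(frozen=True)
class YoudenResult:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


def youden_cutoff(scores: Sequence[float], outcomes: Sequence[int]) -> YoudenResult:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    Candidate thresholds are the unique observed scores (test positive when
    score ≥ threshold); ties on J are broken toward the higher threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n1 = y.sum()
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one case and one control")
    best = None
    for thr in np.unique(s):
        pos = s >= thr
        sens = float(np.sum(pos & (y == 1)) / n1)
        spec = float(np.sum(~pos & (y == 0)) / n0)
        j = sens + spec - 1.0
        if best is None or j >= best.youden_j - 1e-12:
            best = YoudenResult(float(thr), sens, spec, j)
    return best
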