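"""Statistical primitives shared by every pipeline stage.

Conventions used throughout the package:

* t-tests are Welch (unequal-variance) two-sided tests;
* 2x2 chi-squared tests use the Yates continuity correction;
* FDR means Benjamini-Hochberg;
* ROC ties receive half credit (Mann-Whitney convention) and the Youden
  operating point breaks ties toward the lowest cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "RegressionFit",
    "RocCurve",
    "EnrichmentInputs",
    "welch_t_from_summary",
    "welch_t",
    "chi2_yates_2x2",
    "bh_fdr",
    "ols_regression",
    "pearson_test",
    "hypergeom_overrep",
    "roc_auc",
    "youden_point",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or association test.

    ``estimate`` is the test's natural effect quantity: a mean difference for
    t-tests, a correlation coefficient for the Pearson test.
    """

    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    estimate: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit: named coefficients with classical standard errors."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    n: int
    residual_df: int

    def __getitem__(self, name: str) -> tuple[float, float, float]:
        return (
            self.coefficients[name],
            self.standard_errors[name],
            self.p_values[name],
        )


@dataclass(frozen=True)
class RocCurve:
    """Operating points at every distinct score threshold.

    A sample is called positive when its score is >= the threshold; the
    thresholds are the distinct observed scores plus one above the maximum so
    the curve spans (sens, spec) = (1, 0) .. (0, 1).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float = field(default=np.nan)


@dataclass(frozen=True)
class EnrichmentInputs:
    """Counts entering a hypergeometric over-representation test."""

    overlap_x: int
    module_size_m: int
    pathway_size_k: int
    universe_N: int

    def __post_init__(self) -> None:
        x, m, k, N = (
            self.overlap_x,
            self.module_size_m,
            self.pathway_size_k,
            self.universe_N,
        )
        if not (0 <= x <= min(m, k)):
            raise ValueError(f"overlap {x} outside [0, min({m}, {k})]")
        if m > N or k > N:
            raise ValueError(f"module ({m}) or pathway ({k}) larger than universe ({N})")


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Welch two-sample t-test from group summaries (mean, SD, n)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return TestResult(statistic=0.0, p_value=1.0, df=n1 + n2 - 2, estimate=0.0)
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))  # Welch-Satterthwaite
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(df),
        estimate=float(mean1 - mean2),
    )


def welch_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Welch two-sample t-test on raw vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x) == 0 and np.var(y) == 0:
        if x.mean() == y.mean():
            return TestResult(statistic=0.0, p_value=1.0, df=x.size + y.size - 2, estimate=0.0)
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        estimate=float(x.mean() - y.mean()),
    )


def chi2_yates_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Yates continuity-corrected chi-squared test of a 2x2 table [[a, b], [c, d]].

    The correction term |ad - bc| - n/2 is clipped at zero; p is the
    upper tail of chi-squared with 1 df.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("cell counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("both margins of the 2x2 table must be positive")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=True)
    return TestResult(statistic=float(chi2), p_value=float(p), df=float(dof))


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ols_regression(y: np.ndarray, design: pd.DataFrame) -> RegressionFit:
    """Ordinary least squares with classical SEs and two-sided t-based p-values.

    ``design`` must carry named columns (include an intercept column
    explicitly if one is wanted).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    names = list(design.columns)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n = {n} must exceed the {k} design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the columns involved in the deficiency for the error message
        bad = []
        for j in range(k):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ValueError(f"design is rank deficient; collinear columns: {bad or names}")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * sps.t.sf(np.abs(tvals), dof)
    return RegressionFit(
        coefficients=dict(zip(names, beta.astype(float))),
        standard_errors=dict(zip(names, se.astype(float))),
        p_values=dict(zip(names, pvals.astype(float))),
        n=n,
        residual_df=dof,
    )


def pearson_test(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Pearson correlation with the t-transform two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant vector has undefined correlation")
    r, p = sps.pearsonr(x, y)
    return TestResult(statistic=float(r), p_value=float(p), df=float(x.size - 2), estimate=float(r))


def hypergeom_overrep(inputs: EnrichmentInputs) -> float:
    """Upper-tail hypergeometric p-value P(X >= x).

    X counts pathway members inside a module of size m drawn without
    replacement from a universe of N features, k of which belong to the
    pathway.
    """
    x, m, k, N = (
        inputs.overlap_x,
        inputs.module_size_m,
        inputs.pathway_size_k,
        inputs.universe_N,
    )
    return float(sps.hypergeom.sf(x - 1, N, k, m))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, RocCurve]:
    """AUC (half credit for ties) and the full ROC operating-point curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # Mann-Whitney pair counting with half credit for ties, via midranks
    ranks = sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    distinct = np.unique(scores)
    thresholds = np.concatenate([distinct, [distinct[-1] + 1.0]])
    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    for i, thr in enumerate(thresholds):
        sens[i] = np.mean(pos_scores >= thr)
        spec[i] = np.mean(neg_scores < thr)
    curve = RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=float(auc))
    return float(auc), curve


def youden_point(
    curve: RocCurve, scores: np.ndarray, labels: np.ndarray
) -> dict[str, float]:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Ties in J break toward the lowest cutoff. PPV/NPV are computed at the
    chosen cutoff (positive call: score >= cutoff); an undefined predictive
    value (empty call set) is reported as NaN.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best = int(np.argmax(j))  # argmax takes the first (lowest) threshold on ties
    cutoff = float(curve.thresholds[best])
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    called = scores >= cutoff
    tp = int(np.sum(called & (labels == 1)))
    fp = int(np.sum(called & (labels == 0)))
    fn = int(np.sum(~called & (labels == 1)))
    tn = int(np.sum(~called & (labels == 0)))
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    return {
        "J": float(j[best]),
        "cutoff": cutoff,
        "sensitivity": float(curve.sensitivity[best]),
        "specificity": float(curve.specificity[best]),
        "ppv": ppv,
        "npv": npv,
    }
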