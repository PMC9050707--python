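"""Multi-metabolite composite score via penalized logistic regression.

Candidate features are ranked by Welch t-test p-value inside the training
set; the top K enter an elastic-net logistic model whose mixing parameter
(alpha, the L1/L2 blend) and penalty strength (lambda) are tuned by
stratified fivefold cross-validated AUC on the training set. The fitted
score is then evaluated once on the held-out test set (AUC plus the Youden
operating point). Model selection across the (K, panel) grid follows the
test-AUC-maximizing rule; the grid report should be read with the caveat
that picking the best test-set cell is optimistically biased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from . import stats as mstats
from .stats import RegressionFit, RocCurve
from .differential import build_design

__all__ = [
    "CompositeScoreModel",
    "CompositeResults",
    "EvaluationReport",
    "rank_by_ttest",
    "select_best_model",
    "score_group_association",
    "DEFAULT_K_GRID",
]

#: K = 2..10, 20..100 by 10, 200..500 by 100, plus all features
DEFAULT_K_GRID: tuple[object, ...] = tuple(
    list(range(2, 11)) + list(range(20, 101, 10)) + list(range(200, 501, 100)) + ["all"]
)

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


def rank_by_ttest(
    train_matrix: pd.DataFrame,
    train_labels: pd.Series | np.ndarray,
    annotation: pd.DataFrame | None = None,
    panel: str | None = None,
) -> list[str]:
    """Features ordered by ascending Welch p (ties: lexicographic id).

    Computed on training samples only; the panel filter restricts candidates
    before ranking.
    """
    y = np.asarray(train_labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = train_matrix
    if panel is not None and panel != "combined":
        if annotation is None:
            raise ValueError("panel filtering requires an annotation table")
        keep = annotation.index[annotation["panel"] == panel]
        keep = [f for f in X.columns if f in set(keep)]
        if not keep:
            raise ValueError(f"no features in panel {panel!r}")
        X = X[keep]
    a = X.to_numpy()[y == 1]
    b = X.to_numpy()[y == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(a, b, equal_var=False, axis=0)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    order = sorted(zip(p, X.columns), key=lambda t: (t[0], t[1]))
    return [f for _, f in order]


@dataclass
class EvaluationReport:
    """Held-out performance of a fitted composite score."""

    auc: float
    curve: RocCurve
    youden: dict[str, float]
    scores: pd.Series

    def summary(self) -> str:
        y = self.youden
        return (
            f"test AUC = {self.auc:.3f}; Youden J = {y['J']:.3f} at cutoff "
            f"{y['cutoff']:.3f} (sens {y['sensitivity']:.3f}, spec "
            f"{y['specificity']:.3f}, PPV {y['ppv']:.3f}, NPV {y['npv']:.3f})"
        )


@dataclass
class CompositeResults:
    """Fitted elastic-net composite: features, weights and tuning choices."""

    features: list[str]
    weights: pd.Series
    intercept: float
    alpha: float
    lam: float
    cv_auc: float
    train_mean: pd.Series
    train_sd: pd.Series
    panel: str | None
    K: int | str

    @property
    def selected_features(self) -> list[str]:
        return list(self.weights.index[self.weights != 0.0])

    def score(self, matrix: pd.DataFrame) -> pd.Series:
        """Linear composite score using training standardization."""
        missing = [f for f in self.features if f not in matrix.columns]
        if missing:
            raise ValueError(f"features absent from matrix: {missing[:10]}")
        Xs = (matrix[self.features] - self.train_mean) / self.train_sd
        return pd.Series(
            Xs.to_numpy() @ self.weights.to_numpy() + self.intercept,
            index=matrix.index,
            name="composite_score",
        )

    def evaluate(
        self, test_matrix: pd.DataFrame, test_labels: pd.Series | np.ndarray
    ) -> EvaluationReport:
        scores = self.score(test_matrix)
        y = np.asarray(test_labels).astype(int)
        auc, curve = mstats.roc_auc(scores.to_numpy(), y)
        youden = mstats.youden_point(curve, scores.to_numpy(), y)
        return EvaluationReport(auc=auc, curve=curve, youden=youden, scores=scores)

    def summary(self) -> str:
        nz = self.selected_features
        return (
            f"Composite score [panel={self.panel or 'combined'}, K={self.K}]: "
            f"{len(nz)}/{len(self.features)} features with nonzero weight; "
            f"alpha={self.alpha:.2f}, lambda={self.lam:.4g}, CV AUC={self.cv_auc:.3f}"
        )


def _lambda_path(Xs: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int,
                 min_ratio: float) -> np.ndarray:
    """glmnet-style log-spaced penalty path from the all-zero solution down."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.max(np.abs(Xs.T @ resid)) / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _fit_enet(Xs, y, alpha, lam, warm=None):
    n = len(y)
    clf = warm or LogisticRegression(
        penalty="elasticnet",
        solver="saga",
        l1_ratio=alpha,
        C=1.0,
        max_iter=3000,
        tol=1e-4,
        warm_start=True,
        random_state=0,  # saga shuffling; fixed for exact reproducibility
    )
    clf.l1_ratio = alpha
    clf.C = 1.0 / (n * lam)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xs, y)
    return clf


class CompositeScoreModel:
    """Elastic-net logistic composite over the top-K ranked features.

    Test data must never leak into this model: ranking, standardization and
    tuning all see the training samples only.
    """

    def __init__(
        self,
        train_matrix: pd.DataFrame,
        train_labels: pd.Series | np.ndarray,
        K: int | str = "all",
        panel: str | None = None,
        annotation: pd.DataFrame | None = None,
        alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
        n_lambda: int = 50,
        lambda_min_ratio: float = 1e-3,
        n_folds: int = 5,
        seed: int = 0,
    ) -> None:
        self.train_matrix = train_matrix
        self.train_labels = np.asarray(train_labels).astype(int)
        self.K = K
        self.panel = panel
        self.annotation = annotation
        self.alpha_grid = tuple(alpha_grid)
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.n_folds = n_folds
        self.seed = seed

    def _candidates(self) -> list[str]:
        ranked = rank_by_ttest(
            self.train_matrix, self.train_labels, self.annotation, self.panel
        )
        if self.K == "all":
            return ranked
        if int(self.K) > len(ranked):
            raise ValueError(f"K={self.K} exceeds the {len(ranked)} available features")
        return ranked[: int(self.K)]

    def _folds(self, y: np.ndarray):
        for attempt in range(5):
            skf = StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.seed + attempt
            )
            folds = list(skf.split(np.zeros(len(y)), y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
                return folds
        raise ValueError("could not build folds containing both classes")

    def fit(self) -> CompositeResults:
        feats = self._candidates()
        y = self.train_labels
        X = self.train_matrix[feats]
        mean = X.mean()
        sd = X.std(ddof=1).replace(0.0, 1.0)
        Xs = ((X - mean) / sd).to_numpy()

        folds = self._folds(y)
        best = None  # (cv_auc, lam, alpha)
        for alpha in self.alpha_grid:
            lams = _lambda_path(Xs, y, alpha, self.n_lambda, self.lambda_min_ratio)
            fold_scores = np.zeros((len(folds), len(lams)))
            for fi, (tr, te) in enumerate(folds):
                clf = None
                for li, lam in enumerate(lams):
                    clf = _fit_enet(Xs[tr], y[tr], alpha, lam, warm=clf)
                    prob = Xs[te] @ clf.coef_.ravel() + clf.intercept_[0]
                    if len(np.unique(y[te])) == 2 and np.ptp(prob) > 0:
                        auc, _ = mstats.roc_auc(prob, y[te])
                    elif len(np.unique(y[te])) == 2:
                        auc = 0.5
                    else:  # degenerate held-out fold: uninformative
                        auc = np.nan
                    fold_scores[fi, li] = auc
            mean_auc = np.nanmean(fold_scores, axis=0)
            for li, lam in enumerate(lams):
                cand = (mean_auc[li], lam, alpha)
                # ties prefer sparser (larger lambda), then more L1 (larger alpha)
                if best is None or cand > best:
                    best = cand
        cv_auc, lam, alpha = best
        clf = _fit_enet(Xs, y, alpha, lam)
        return CompositeResults(
            features=feats,
            weights=pd.Series(clf.coef_.ravel(), index=feats),
            intercept=float(clf.intercept_[0]),
            alpha=float(alpha),
            lam=float(lam),
            cv_auc=float(cv_auc),
            train_mean=mean,
            train_sd=sd,
            panel=self.panel,
            K=self.K,
        )


def select_best_model(
    train_matrix: pd.DataFrame,
    train_labels: pd.Series | np.ndarray,
    test_matrix: pd.DataFrame,
    test_labels: pd.Series | np.ndarray,
    annotation: pd.DataFrame | None = None,
    K_grid: tuple[object, ...] = DEFAULT_K_GRID,
    panels: tuple[str | None, ...] = ("HD4", "CLP", "combined"),
    seed: int = 0,
    **model_kwargs,
) -> tuple[CompositeResults, EvaluationReport, pd.DataFrame]:
    """Fit every (K, panel) cell and return the cell with the largest test AUC.

    Grid cells whose K exceeds the panel's feature count are skipped. The
    returned grid table carries every cell's CV and test AUC; because the
    winner is chosen on the test set, its AUC is an optimistic estimate.
    """
    rows = []
    best = None
    for panel in panels:
        panel_arg = None if panel in (None, "combined") else panel
        for K in K_grid:
            try:
                model = CompositeScoreModel(
                    train_matrix,
                    train_labels,
                    K=K,
                    panel=panel_arg,
                    annotation=annotation,
                    seed=seed,
                    **model_kwargs,
                )
                res = model.fit()
            except ValueError:
                continue  # K larger than the candidate pool
            report = res.evaluate(test_matrix, test_labels)
            rows.append(
                {
                    "panel": panel or "combined",
                    "K": K,
                    "cv_auc": res.cv_auc,
                    "test_auc": report.auc,
                    "n_selected": len(res.selected_features),
                }
            )
            key = (report.auc, res.cv_auc)
            if best is None or key > best[0]:
                best = (key, res, report)
    if best is None:
        raise ValueError("no grid cell could be fitted")
    grid = pd.DataFrame(rows)
    return best[1], best[2], grid


def score_group_association(
    scores: pd.Series,
    samples: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "race", "bmi"),
) -> RegressionFit:
    """Regress the standardized composite score on group + covariates."""
    if not scores.index.equals(samples.index):
        if set(scores.index) != set(samples.index):
            raise ValueError("scores and samples are not aligned")
        scores = scores.loc[samples.index]
    design = build_design(samples, covariates)
    z = (scores - scores.mean()) / scores.std()
    return mstats.ols_regression(z.to_numpy(), design)
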