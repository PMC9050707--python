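"""Consensus independent component analysis for co-abundance modules.

The decomposition treats FEATURES as observations: each independent
component is a source-signal vector over features (unit SD), and the
per-sample mixing weights serve as the module's activity scores for trait
regression. Module membership is the classic 2-SD rule on |source signal|.

Robustness follows a multi-restart consensus: the fixed-point ICA is run
many times from different random starts, components of the first converged
(reference) run are matched one-to-one to every other run by maximal |Pearson
r| (Hungarian assignment), and a component is retained only when it is
reproduced closely in a large fraction of runs. ICA leaves the sign of each
component arbitrary, so retained components are re-oriented to positive
skewness of the source signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .differential import DifferentialModel

__all__ = [
    "select_component_count",
    "fastica_run",
    "ConsensusICA",
    "ICAResults",
    "ModuleSet",
]


def select_component_count(
    matrix: pd.DataFrame, variance_fraction: float = 0.80
) -> int:
    """Smallest component count whose principal variance reaches the target.

    The matrix is centered per feature; with ``variance_fraction=1.0`` this
    returns the numerical rank.
    """
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must lie in (0, 1]")
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    sv = np.linalg.svd(X, compute_uv=False)
    var = sv**2
    tol = sv.max() * max(X.shape) * np.finfo(float).eps
    var = var[sv > tol]
    frac = np.cumsum(var) / var.sum()
    return int(np.searchsorted(frac, variance_fraction - 1e-12) + 1)


def fastica_run(
    matrix: pd.DataFrame, q: int, seed: int
) -> dict[str, np.ndarray | bool]:
    """One fixed-point ICA restart (symmetric, logcosh contrast).

    Returns unit-SD source signals over features (p x q), per-sample mixing
    weights (n x q) and a convergence flag. Whitening reduces to ``q``
    principal dimensions first.
    """
    n, p = matrix.shape
    if q > min(n, p):
        raise ValueError(f"q={q} exceeds matrix rank bound {min(n, p)}")
    # center per feature: mean abundance is a constant-across-samples direction
    # that would otherwise absorb a whitened dimension
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    ica = FastICA(
        n_components=q,
        algorithm="parallel",
        fun="logcosh",
        fun_args={"alpha": 1.0},
        whiten="unit-variance",
        tol=1e-4,
        max_iter=200,
        random_state=int(seed),
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(X.T)  # (p, q)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    mixing = ica.mixing_  # (n, q)
    sd = sources.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    sources = sources / sd
    mixing = mixing * sd
    return {"sources": sources, "mixing": mixing, "converged": converged}


def _match_components(ref: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one assignment of columns maximizing total |Pearson r|."""
    a = ref - ref.mean(axis=0)
    b = other - other.mean(axis=0)
    a = a / np.linalg.norm(a, axis=0)
    b = b / np.linalg.norm(b, axis=0)
    corr = a.T @ b
    rows, cols = linear_sum_assignment(-np.abs(corr))
    matched_r = np.abs(corr[rows, cols])
    return cols[np.argsort(rows)], matched_r[np.argsort(rows)]


@dataclass
class ModuleSet:
    """Feature memberships of retained components under the |signal| > k*SD rule."""

    members: dict[str, list[str]]
    thresholds: dict[str, float]
    sd_multiplier: float

    def __iter__(self):
        return iter(self.members.items())

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ICAResults:
    """Retained consensus components with reproducibility diagnostics."""

    sources: pd.DataFrame  # features x components, unit SD
    sample_scores: pd.DataFrame  # samples x components
    run_support: pd.DataFrame  # per component: support fraction, mean matched |r|
    q: int
    n_runs: int
    n_converged: int
    master_seed: int

    def modules(self, sd_multiplier: float = 2.0) -> ModuleSet:
        """Members per component: features beyond ``sd_multiplier`` source SDs."""
        members = {}
        thresholds = {}
        for comp in self.sources.columns:
            s = self.sources[comp]
            thr = sd_multiplier * float(s.std(ddof=0))
            members[comp] = list(s.index[np.abs(s) > thr])
            thresholds[comp] = thr
        return ModuleSet(members=members, thresholds=thresholds, sd_multiplier=sd_multiplier)

    def trait_association(
        self,
        samples: pd.DataFrame,
        covariates: tuple[str, ...] = ("age", "race", "bmi"),
        p_threshold: float = 0.05,
    ) -> pd.DataFrame:
        """Per-component regression of standardized activity on group + covariates.

        Component sign is a convention (positive source skewness), so only
        |coef| is directional-free; the significant set uses the two-sided p.
        """
        if not self.sample_scores.index.equals(samples.index):
            raise ValueError("sample scores and sample table are not aligned")
        res = DifferentialModel(
            self.sample_scores, samples, covariates, context="module_trait"
        ).fit()
        out = res.table.rename_axis("component")
        out["significant"] = out["p"] < p_threshold
        return out

    def summary(self) -> str:
        lines = [
            f"Consensus ICA: q={self.q}, {len(self.sources.columns)} retained "
            f"components from {self.n_converged}/{self.n_runs} converged runs",
            self.run_support.to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


class ConsensusICA:
    """Multi-restart ICA with consensus retention of reproducible components.

    Parameters
    ----------
    matrix : samples x features table (batch-adjusted, standardized upstream).
    q : component count; defaults to the smallest count reaching
        ``variance_fraction`` of the principal variance.
    n_runs : number of random restarts (50 by default).
    match_r, support_frac : a reference component is retained when matched at
        |r| >= ``match_r`` in at least ``support_frac`` of converged runs.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        q: int | None = None,
        variance_fraction: float = 0.80,
        n_runs: int = 50,
        match_r: float = 0.90,
        support_frac: float = 0.80,
        master_seed: int = 0,
    ) -> None:
        self.matrix = matrix
        self.q = q
        self.variance_fraction = variance_fraction
        self.n_runs = n_runs
        self.match_r = match_r
        self.support_frac = support_frac
        self.master_seed = master_seed

    def fit(self) -> ICAResults:
        q = self.q or select_component_count(self.matrix, self.variance_fraction)
        rng = np.random.default_rng(self.master_seed)
        seeds = rng.integers(0, 2**31 - 1, size=self.n_runs)
        runs = [fastica_run(self.matrix, q, s) for s in seeds]
        converged = [r for r in runs if r["converged"]]
        if not converged:
            raise RuntimeError("no ICA restart converged; increase max_iter or lower q")
        ref = converged[0]
        support_counts = np.ones(q)  # the reference matches itself
        sum_r = np.ones(q)
        for other in converged[1:]:
            _, matched_r = _match_components(ref["sources"], other["sources"])
            support_counts += matched_r >= self.match_r
            sum_r += matched_r
        support = support_counts / len(converged)
        mean_r = sum_r / len(converged)
        retained = np.where(support >= self.support_frac)[0]
        if len(converged) == 1:
            retained = np.arange(q)

        names = [f"IC{i + 1}" for i in range(len(retained))]
        sources = ref["sources"][:, retained].copy()
        mixing = ref["mixing"][:, retained].copy()
        for j in range(sources.shape[1]):
            sk = skew(sources[:, j])
            if sk < 0 or (sk == 0 and sources[np.argmax(np.abs(sources[:, j])), j] < 0):
                sources[:, j] *= -1
                mixing[:, j] *= -1
        return ICAResults(
            sources=pd.DataFrame(sources, index=self.matrix.columns, columns=names),
            sample_scores=pd.DataFrame(mixing, index=self.matrix.index, columns=names),
            run_support=pd.DataFrame(
                {"support": support[retained], "mean_abs_r": mean_r[retained]},
                index=names,
            ),
            q=q,
            n_runs=self.n_runs,
            n_converged=len(converged),
            master_seed=self.master_seed,
        )
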