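"""Per-feature differential abundance with a discovery/replication design.

Each feature is regressed on group status with adjustment for age, race and
BMI. Features and continuous covariates are standardized within the analysis
context, so the reported group coefficient is a standardized effect size.
Discovery hits are declared at FDR < 0.1 and count as replicated when the
replication p-value is below 0.05 with the same coefficient sign; the
combined analysis pools the subsamples after empirical-Bayes batch
adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as mstats
from .io import Dataset, split_subsamples
from .preprocess import combat_adjust, standardize_columns

__all__ = [
    "DifferentialModel",
    "DifferentialResults",
    "discovery_replication_workflow",
    "run_discovery_replication",
    "sensitivity_analysis",
    "class_direction_tally",
]

DEFAULT_COVARIATES = ("age", "race", "bmi")


def build_design(
    samples: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    standardize: bool = True,
) -> pd.DataFrame:
    """Design matrix [const, group, covariates...] for association fits.

    ``group`` is 1 for cases; ``race`` becomes a caucasian indicator.
    Continuous covariates are standardized (sample SD) when requested. A
    covariate that is constant in these samples carries no adjustment
    information and is dropped with a warning rather than breaking the fit.
    """
    cols: dict[str, np.ndarray] = {
        "const": np.ones(len(samples)),
        "group": (samples["group"] == "case").to_numpy(dtype=float),
    }
    for cov in covariates:
        if cov == "race":
            vals = (samples["race"] == "caucasian").astype(float)
            name = "race_caucasian"
        else:
            raw = samples[cov]
            vals = raw.astype(float) if raw.dtype != bool else raw.astype(float)
            name = cov
        if vals.nunique() <= 1:
            warnings.warn(f"covariate {cov!r} is constant here; dropped", stacklevel=2)
            continue
        if standardize and cov != "race" and vals.nunique() > 2:
            vals = (vals - vals.mean()) / vals.std()
        cols[name] = vals.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=samples.index)


@dataclass
class DifferentialResults:
    """Per-feature group effects with BH-adjusted q-values."""

    table: pd.DataFrame  # index feature_id: coef, se, p, q
    context: str
    covariates: tuple[str, ...]
    n: int

    def hits(self, fdr: float = 0.1) -> pd.DataFrame:
        return self.table[self.table["q"] < fdr]

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("p").head(top)
        lines = [
            f"Differential analysis [{self.context}]  n={self.n}, "
            f"features={len(self.table)}, covariates={list(self.covariates)}",
            f"hits at FDR<0.1: {int((self.table['q'] < 0.1).sum())}",
            t.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


class DifferentialModel:
    """Per-feature OLS of abundance on group + covariates.

    The fit is vectorized over features: all features share one design
    matrix, so a single least-squares solve yields every coefficient, and the
    result agrees exactly with a feature-by-feature
    :func:`metabomod.stats.ols_regression` (asserted in the test suite).
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        samples: pd.DataFrame,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        standardize: bool = True,
        context: str = "analysis",
    ) -> None:
        if not matrix.index.equals(samples.index):
            matrix = matrix.loc[samples.index]
        self.matrix = matrix
        self.samples = samples
        self.covariates = tuple(covariates)
        self.standardize = standardize
        self.context = context

    def fit(self) -> DifferentialResults:
        Y = self.matrix
        if self.standardize:
            Y = standardize_columns(Y)
        design = build_design(self.samples, self.covariates, standardize=self.standardize)
        X = design.to_numpy()
        n, k = X.shape
        if n <= k:
            raise ValueError(f"n = {n} too small for {k} design columns")
        if np.linalg.matrix_rank(X) < k:
            raise ValueError(f"collinear design columns among {list(design.columns)}")
        xtx_inv = np.linalg.inv(X.T @ X)
        B = xtx_inv @ X.T @ Y.to_numpy()
        resid = Y.to_numpy() - X @ B
        dof = n - k
        sigma2 = (resid**2).sum(axis=0) / dof
        g = list(design.columns).index("group")
        coef = B[g]
        se = np.sqrt(sigma2 * xtx_inv[g, g])
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, coef / se, 0.0)
        p = 2 * sps.t.sf(np.abs(tval), dof)
        q = mstats.bh_fdr(p)
        table = pd.DataFrame(
            {"coef": coef, "se": se, "p": p, "q": q},
            index=Y.columns.rename("feature_id"),
        )
        return DifferentialResults(
            table=table, context=self.context, covariates=self.covariates, n=n
        )


def discovery_replication_workflow(
    disc: DifferentialResults,
    rep: DifferentialResults,
    combined: DifferentialResults | None = None,
    fdr: float = 0.1,
    replication_p: float = 0.05,
) -> pd.DataFrame:
    """Merge discovery/replication (and optionally combined) fits with flags.

    ``discovery_hit``: discovery q < ``fdr``. ``consistent_direction``: same
    coefficient sign in both subsamples. ``replicated``: a discovery hit with
    replication p < ``replication_p`` AND consistent sign.
    """
    if set(disc.table.index) != set(rep.table.index):
        raise ValueError("discovery and replication feature universes differ")
    out = disc.table.add_suffix("_discovery").join(
        rep.table.loc[disc.table.index].add_suffix("_replication")
    )
    if combined is not None:
        if set(combined.table.index) != set(disc.table.index):
            raise ValueError("combined feature universe differs")
        out = out.join(combined.table.loc[out.index].add_suffix("_combined"))
    out["discovery_hit"] = out["q_discovery"] < fdr
    out["consistent_direction"] = (
        np.sign(out["coef_discovery"]) == np.sign(out["coef_replication"])
    )
    out["replicated"] = (
        out["discovery_hit"]
        & (out["p_replication"] < replication_p)
        & out["consistent_direction"]
    )
    return out


def run_discovery_replication(
    dataset: Dataset,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    fdr: float = 0.1,
    replication_p: float = 0.05,
) -> dict[str, object]:
    """Full design: per-subsample fits plus the batch-adjusted combined fit.

    Combined analysis order: pool -> empirical-Bayes batch adjustment with
    subsample as the batch label (covariates adjusted for, group label
    excluded) -> standardize -> fit.
    """
    disc, rep = split_subsamples(dataset)
    disc_res = DifferentialModel(
        disc.abundance, disc.samples, covariates, context="discovery"
    ).fit()
    rep_res = DifferentialModel(
        rep.abundance, rep.samples, covariates, context="replication"
    ).fit()
    cov_design = build_design(dataset.samples, covariates).drop(
        columns=["const", "group"]
    )
    adjusted, batch_model = combat_adjust(
        dataset.abundance, dataset.samples["subsample"], covariates=cov_design
    )
    comb_res = DifferentialModel(
        adjusted, dataset.samples, covariates, context="combined"
    ).fit()
    table = discovery_replication_workflow(
        disc_res, rep_res, comb_res, fdr=fdr, replication_p=replication_p
    )
    return {
        "discovery": disc_res,
        "replication": rep_res,
        "combined": comb_res,
        "batch_model": batch_model,
        "table": table,
    }


def sensitivity_analysis(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    base_covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    extra: str = "hypertension",
    features: list[str] | None = None,
    context: str | None = None,
) -> DifferentialResults | None:
    """Refit the group association with one additional covariate.

    Returns ``None`` (with a warning) when the extra covariate is constant;
    collinearity with the group label raises inside the fit.
    """
    col = samples[extra]
    if col.nunique() <= 1:
        warnings.warn(f"sensitivity covariate {extra!r} is constant; skipped", stacklevel=2)
        return None
    sub = matrix[features] if features is not None else matrix
    return DifferentialModel(
        sub,
        samples,
        covariates=tuple(base_covariates) + (extra,),
        context=context or f"sensitivity+{extra}",
    ).fit()


def class_direction_tally(
    table: pd.DataFrame,
    annotation: pd.DataFrame,
    class_field: str,
    class_value: str,
    coef_col: str = "coef",
    q_col: str = "q",
    fdr: float = 0.1,
) -> dict[str, int]:
    """Coefficient-sign and significance counts within one annotation class.

    The kind of summary behind statements like "57 of 61 sphingolipids were
    higher in cases".
    """
    if class_field not in annotation.columns:
        raise ValueError(f"unknown annotation field {class_field!r}")
    members = annotation.index[annotation[class_field] == class_value]
    members = members.intersection(table.index)
    if len(members) == 0:
        raise ValueError(f"no features in class {class_value!r}")
    sub = table.loc[members]
    return {
        "n_total": int(len(sub)),
        "n_positive": int((sub[coef_col] > 0).sum()),
        "n_negative": int((sub[coef_col] < 0).sum()),
        "n_significant": int((sub[q_col] < fdr).sum()),
    }
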