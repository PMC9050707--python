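"""Imputation, transformation, standardization and batch adjustment.

The batch adjustment is a parametric empirical-Bayes location/scale model in
the ComBat family: per feature, batch means are shrunk toward a common batch
mean under a normal prior and batch variances toward a common variance under
an inverse-gamma prior, with hyperparameters estimated by the method of
moments and the conditional posteriors solved by fixed-point iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BatchModel",
    "impute_and_log",
    "standardize_columns",
    "combat_adjust",
]


@dataclass
class BatchModel:
    """Fitted batch-adjustment parameters, one row per (batch, feature)."""

    batches: list[str]
    gamma_star: pd.DataFrame  # batches x features, EB-shrunk location
    delta2_star: pd.DataFrame  # batches x features, EB-shrunk scale (variance)
    gamma_bar: pd.Series  # per-batch prior mean of locations
    tau2: pd.Series  # per-batch prior variance of locations
    a_prior: pd.Series  # per-batch inverse-gamma shape
    b_prior: pd.Series  # per-batch inverse-gamma scale
    covariates: list[str]


def impute_and_log(
    matrix: pd.DataFrame,
    batch: pd.Series | None = None,
    already_logged: bool = True,
) -> pd.DataFrame:
    """Fill missing cells with the per-feature minimum observed in the same batch.

    Minimum imputation encodes the assumption that missingness reflects
    abundances below the detection limit. With ``already_logged=False`` the
    values are natural-log transformed after imputation (requires positive
    values). Non-missing cells are never altered beyond the log map.
    """
    out = matrix.copy().astype(float)
    groups = (
        [(None, out.index)]
        if batch is None
        else [(b, out.index[batch.loc[out.index] == b]) for b in pd.unique(batch.loc[out.index])]
    )
    for label, idx in groups:
        block = out.loc[idx]
        all_missing = block.columns[block.isna().all(axis=0)]
        if len(all_missing) > 0:
            where = f" in batch {label!r}" if label is not None else ""
            raise ValueError(
                f"features entirely missing{where}: {list(all_missing)[:10]}"
            )
        out.loc[idx] = block.fillna(block.min(axis=0))
    if not already_logged:
        if (out <= 0).any().any():
            raise ValueError("log transform requires strictly positive values")
        out = np.log(out)
    return out


def standardize_columns(
    values: pd.DataFrame | pd.Series,
    within: pd.Series | None = None,
    ddof: int = 1,
) -> pd.DataFrame | pd.Series:
    """Scale each column to mean 0, SD 1 (sample SD), optionally per group.

    ``within`` gives a group label per row; standardization then happens
    inside each group separately (the analysis-subsample convention).
    Constant columns are an error, named in the message.
    """
    if isinstance(values, pd.Series):
        return standardize_columns(values.to_frame(), within=within, ddof=ddof).iloc[:, 0]
    out = values.astype(float).copy()
    groups = (
        [out.index]
        if within is None
        else [out.index[within.loc[out.index] == g] for g in pd.unique(within.loc[out.index])]
    )
    for idx in groups:
        block = out.loc[idx]
        sd = block.std(ddof=ddof)
        constant = sd.index[(sd == 0) | sd.isna()].tolist()
        if constant:
            raise ValueError(f"constant columns cannot be standardized: {constant[:10]}")
        out.loc[idx] = (block - block.mean()) / sd
    return out


def _moments_inverse_gamma(delta_hat: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inverse-gamma hyperparameters for batch variances."""
    m = float(np.mean(delta_hat))
    s2 = float(np.var(delta_hat, ddof=1))
    if s2 <= 0:
        return np.inf, np.inf
    a = (2 * s2 + m**2) / s2
    b = (m * s2 + m**3) / s2
    return a, b


def combat_adjust(
    matrix: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[pd.DataFrame, BatchModel]:
    """Remove additive and multiplicative batch effects, empirical-Bayes style.

    Per feature the model is ``y = alpha + X beta + gamma_batch +
    delta_batch * eps``. Batch locations and scales are estimated after
    removing the covariate fit, shrunk across features within each batch
    (normal prior on locations, inverse-gamma on variances), and the data are
    returned on the original scale with covariate effects restored.

    The group label is deliberately NOT part of ``covariates`` by default:
    with groups balanced across batches, leaving it out cannot absorb group
    signal into the batch estimate.
    """
    batch = batch.loc[matrix.index]
    levels = [str(b) for b in pd.unique(batch)]
    if len(levels) == 1:
        warnings.warn("single batch: adjustment is the identity", stacklevel=2)
        model = BatchModel(
            batches=levels,
            gamma_star=pd.DataFrame(0.0, index=levels, columns=matrix.columns),
            delta2_star=pd.DataFrame(1.0, index=levels, columns=matrix.columns),
            gamma_bar=pd.Series(0.0, index=levels),
            tau2=pd.Series(0.0, index=levels),
            a_prior=pd.Series(np.nan, index=levels),
            b_prior=pd.Series(np.nan, index=levels),
            covariates=list(covariates.columns) if covariates is not None else [],
        )
        return matrix.copy(), model
    counts = batch.value_counts()
    small = counts.index[counts < 3].tolist()
    if small:
        raise ValueError(f"batches with fewer than 3 samples: {small}")

    Y = matrix.to_numpy(dtype=float)
    n, p = Y.shape
    onehot = pd.get_dummies(batch.astype(str))[levels].to_numpy(dtype=float)
    if covariates is not None and covariates.shape[1] > 0:
        X_cov = covariates.loc[matrix.index].to_numpy(dtype=float)
        design = np.hstack([onehot, X_cov])
    else:
        X_cov = np.zeros((n, 0))
        design = onehot
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("batch + covariate design is rank deficient "
                         "(is the batch label among the covariates?)")

    beta_full, *_ = np.linalg.lstsq(design, Y, rcond=None)
    n_batches = len(levels)
    batch_props = onehot.mean(axis=0)
    grand = batch_props @ beta_full[:n_batches]  # weighted grand mean per feature
    cov_fit = X_cov @ beta_full[n_batches:] if X_cov.shape[1] else 0.0

    resid = Y - design @ beta_full
    pooled_var = np.mean(resid**2, axis=0)
    pooled_var = np.where(pooled_var <= 0, 1e-12, pooled_var)
    pooled_sd = np.sqrt(pooled_var)

    Z = (Y - grand - cov_fit) / pooled_sd

    gamma_hat = np.empty((n_batches, p))
    delta2_hat = np.empty((n_batches, p))
    for i, lev in enumerate(levels):
        rows = onehot[:, i].astype(bool)
        gamma_hat[i] = Z[rows].mean(axis=0)
        delta2_hat[i] = Z[rows].var(axis=0, ddof=1)
    delta2_hat = np.where(delta2_hat <= 0, 1e-12, delta2_hat)

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    a_prior = np.empty(n_batches)
    b_prior = np.empty(n_batches)
    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    for i in range(n_batches):
        a_prior[i], b_prior[i] = _moments_inverse_gamma(delta2_hat[i])
        n_i = int(onehot[:, i].sum())
        rows = onehot[:, i].astype(bool)
        g = gamma_hat[i].copy()
        d2 = delta2_hat[i].copy()
        for _ in range(max_iter):
            g_new = (n_i * tau2[i] * gamma_hat[i] + d2 * gamma_bar[i]) / (
                n_i * tau2[i] + d2
            )
            sse = ((Z[rows] - g_new) ** 2).sum(axis=0)
            if np.isfinite(a_prior[i]):
                d2_new = (b_prior[i] + 0.5 * sse) / (n_i / 2 + a_prior[i] - 1)
            else:  # flat variance prior: fall back to the batch variance
                d2_new = sse / n_i
            change = max(
                np.max(np.abs(g_new - g)), np.max(np.abs(d2_new - d2))
            )
            g, d2 = g_new, d2_new
            if change < tol:
                break
        gamma_star[i] = g
        delta2_star[i] = np.where(d2 <= 0, 1e-12, d2)

    Z_adj = Z.copy()
    for i in range(n_batches):
        rows = onehot[:, i].astype(bool)
        Z_adj[rows] = (Z[rows] - gamma_star[i]) / np.sqrt(delta2_star[i])
    adjusted = Z_adj * pooled_sd + grand + cov_fit

    model = BatchModel(
        batches=levels,
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=matrix.columns),
        delta2_star=pd.DataFrame(delta2_star, index=levels, columns=matrix.columns),
        gamma_bar=pd.Series(gamma_bar, index=levels),
        tau2=pd.Series(tau2, index=levels),
        a_prior=pd.Series(a_prior, index=levels),
        b_prior=pd.Series(b_prior, index=levels),
        covariates=list(covariates.columns) if covariates is not None else [],
    )
    return pd.DataFrame(adjusted, index=matrix.index, columns=matrix.columns), model
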