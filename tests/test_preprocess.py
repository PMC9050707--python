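"""Imputation, standardization and empirical-Bayes batch adjustment."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from metabomod.preprocess import combat_adjust, impute_and_log, standardize_columns
from metabomod.simulate import SimulationConfig, simulate_dataset
from metabomod.differential import DifferentialModel


def _toy(values, columns=None):
    arr = np.asarray(values, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=columns or [f"f{j}" for j in range(arr.shape[1])],
    )


# ------------------------------------------------------------- imputation


def test_impute_identity_when_complete():
    m = _toy([[1.0, 2.0], [3.0, 4.0]])
    pd.testing.assert_frame_equal(impute_and_log(m), m)


def test_impute_fills_with_in_batch_minimum():
    m = _toy([[1.0, 5.0], [np.nan, 7.0], [4.0, np.nan], [9.0, 2.0]])
    batch = pd.Series(["a", "a", "b", "b"], index=m.index)
    out = impute_and_log(m, batch=batch)
    assert out.loc["s1", "f0"] == 1.0  # batch-a minimum of f0
    assert out.loc["s2", "f1"] == 2.0  # batch-b minimum of f1
    assert not out.isna().any().any()
    # non-missing cells untouched
    mask = ~m.isna().to_numpy()
    assert np.array_equal(out.to_numpy()[mask], m.to_numpy()[mask])


def test_impute_errors_on_fully_missing_feature_in_batch():
    m = _toy([[np.nan, 2.0], [np.nan, 3.0], [1.0, 4.0]])
    batch = pd.Series(["a", "a", "b"], index=m.index)
    with pytest.raises(ValueError, match="f0"):
        impute_and_log(m, batch=batch)


def test_log_transform_applied_when_requested():
    m = _toy([[1.0, np.e], [np.e**2, 1.0]])
    out = impute_and_log(m, already_logged=False)
    assert out.to_numpy() == pytest.approx(np.log(m.to_numpy()))
    with pytest.raises(ValueError):
        impute_and_log(_toy([[0.0, 1.0]]), already_logged=False)


# --------------------------------------------------------- standardization


def test_standardize_matches_sample_sd_convention():
    out = standardize_columns(_toy([[1.0], [2.0], [3.0]]))
    assert out.iloc[:, 0].tolist() == pytest.approx([-1.0, 0.0, 1.0])


def test_standardize_idempotent_and_exact():
    rng = np.random.default_rng(0)
    m = _toy(rng.normal(2.0, 3.0, size=(40, 6)))
    once = standardize_columns(m)
    twice = standardize_columns(once)
    assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)
    assert np.abs(once.mean()).max() < 1e-12
    assert np.abs(once.std(ddof=1) - 1).max() < 1e-12


def test_standardize_within_groups_and_constant_error():
    m = _toy([[1.0], [2.0], [10.0], [20.0]])
    groups = pd.Series(["a", "a", "b", "b"], index=m.index)
    out = standardize_columns(m, within=groups)
    assert out.iloc[:2, 0].mean() == pytest.approx(0.0)
    assert out.iloc[2:, 0].mean() == pytest.approx(0.0)
    with pytest.raises(ValueError, match="f0"):
        standardize_columns(_toy([[1.0], [1.0], [1.0]]))


# ------------------------------------------------------- batch adjustment


def test_combat_single_batch_is_identity_with_warning():
    m = _toy(np.random.default_rng(1).normal(size=(8, 4)))
    batch = pd.Series(["x"] * 8, index=m.index)
    with pytest.warns(UserWarning, match="single batch"):
        adj, model = combat_adjust(m, batch)
    assert np.allclose(adj.to_numpy(), m.to_numpy(), atol=1e-8)


def test_combat_small_batch_rejected():
    m = _toy(np.random.default_rng(1).normal(size=(5, 3)))
    batch = pd.Series(["a", "a", "a", "b", "b"], index=m.index)
    with pytest.raises(ValueError, match="fewer than 3"):
        combat_adjust(m, batch)


def test_combat_removes_pure_location_shift_exactly():
    rng = np.random.default_rng(2)
    v = rng.normal(size=10)
    block = np.tile(v[:, None], (1, 6))
    m = _toy(np.vstack([block, block + 2.0]))
    batch = pd.Series(["a"] * 10 + ["b"] * 10, index=m.index)
    adj, model = combat_adjust(m, batch)
    gap = (adj[batch == "a"].mean() - adj[batch == "b"].mean()).abs().max()
    assert gap < 1e-6
    assert (model.delta2_star > 0).all().all()


def test_combat_reduces_batch_f_statistic():
    from scipy import stats as sps

    cfg = SimulationConfig(
        seed=5, n_features_hd4=60, n_features_clp=60, n_modules=2,
        module_size_range=(5, 8), module_group_effect=(0.0, 0.0),
        singleton_effects={}, batch_shift=1.5, batch_scale=0.1,
    )
    ds, _ = simulate_dataset(cfg)
    labels = ds.samples["subsample"]
    split = lambda mat: [mat[labels == b].to_numpy() for b in ("discovery", "replication")]
    f_before = sps.f_oneway(*split(ds.abundance), axis=0).statistic
    adj, _ = combat_adjust(ds.abundance, labels)
    f_after = sps.f_oneway(*split(adj), axis=0).statistic
    assert np.median(f_after / f_before) < 0.2


def test_combat_preserves_balanced_group_effect():
    cfg = SimulationConfig(
        seed=9, n_features_hd4=100, n_features_clp=100, n_modules=0,
        singleton_effects={f"HD4_{i + 1:04d}": 0.8 for i in range(5)},
        batch_shift=1.5, batch_scale=0.1,
    )
    ref_cfg = SimulationConfig(
        **{**cfg.to_dict(), "batch_shift": 0.0, "batch_scale": 0.0}
    )
    ds, _ = simulate_dataset(cfg)
    ref, _ = simulate_dataset(ref_cfg)
    adj, _ = combat_adjust(ds.abundance, ds.samples["subsample"])
    planted = [f"HD4_{i + 1:04d}" for i in range(5)]
    coef_ref = DifferentialModel(ref.abundance, ref.samples).fit().table.loc[planted, "coef"]
    coef_adj = DifferentialModel(adj, ds.samples).fit().table.loc[planted, "coef"]
    rel = ((coef_adj - coef_ref).abs() / coef_ref.abs()).median()
    assert rel < 0.10


def test_combat_rejects_batch_among_covariates():
    m = _toy(np.random.default_rng(1).normal(size=(12, 4)))
    batch = pd.Series(["a"] * 6 + ["b"] * 6, index=m.index)
    cov = pd.DataFrame({"dup": (batch == "b").astype(float)}, index=m.index)
    with pytest.raises(ValueError, match="rank deficient"):
        combat_adjust(m, batch, covariates=cov)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_combat_matches_bioconductor_sva(tmp_path):
    """Independent oracle: parametric sva::ComBat on a small noisy matrix."""
    rng = np.random.default_rng(21)
    n1, n2, p = 10, 8, 6
    base = rng.normal(5.0, 1.0, size=(n1 + n2, p)) * rng.uniform(0.5, 2.0, size=p)
    base[n1:] += rng.normal(1.0, 0.5, size=p)  # per-feature location shift
    m = _toy(base)
    batch = pd.Series(["a"] * n1 + ["b"] * n2, index=m.index)
    adj, _ = combat_adjust(m, batch)

    data_path = tmp_path / "m.tsv"
    m.T.to_csv(data_path, sep="\t")  # sva expects features x samples
    out_path = tmp_path / "adj.tsv"
    script = tmp_path / "combat.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(sva))
        x <- as.matrix(read.delim("{data_path}", row.names = 1, check.names = FALSE))
        batch <- c(rep("a", {n1}), rep("b", {n2}))
        adj <- ComBat(dat = x, batch = batch, par.prior = TRUE)
        write.table(adj, "{out_path}", sep = "\\t", quote = FALSE)
    """))
    subprocess.run(["Rscript", "--vanilla", str(script)], check=True, capture_output=True)
    r_adj = pd.read_csv(out_path, sep="\t", index_col=0).T
    assert np.allclose(adj.to_numpy(), r_adj.to_numpy(), atol=1e-3)
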