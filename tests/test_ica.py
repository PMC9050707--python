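"""Consensus ICA: component count, single runs, consensus, modules."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from metabomod.ica import (
    ConsensusICA,
    fastica_run,
    select_component_count,
)
from metabomod.preprocess import combat_adjust
from metabomod.differential import build_design
from metabomod.simulate import SimulationConfig, simulate_dataset


def _frame(arr):
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"f{j}" for j in range(arr.shape[1])],
    )


# ----------------------------------------------------- component count


def test_component_count_rank_one():
    rng = np.random.default_rng(0)
    m = _frame(np.outer(rng.normal(size=12), rng.normal(size=30)))
    assert select_component_count(m) == 1


def test_component_count_from_constructed_spectrum():
    """Spectrum with variance shares [0.5, 0.3, 0.15, 0.05] -> q = 2."""
    rng = np.random.default_rng(1)
    n, p, shares = 40, 25, np.array([0.5, 0.3, 0.15, 0.05])
    U, _ = np.linalg.qr(rng.normal(size=(n, 4)))
    V, _ = np.linalg.qr(rng.normal(size=(p, 4)))
    m = _frame((U * np.sqrt(shares)) @ V.T)
    m = m - m.mean(axis=0)
    assert select_component_count(m, 0.80) == 2
    assert select_component_count(m, 1.0) == 4  # numerical rank


def test_component_count_validates_fraction():
    m = _frame(np.random.default_rng(0).normal(size=(6, 6)))
    with pytest.raises(ValueError):
        select_component_count(m, 0.0)
    with pytest.raises(ValueError):
        select_component_count(m, 1.2)


# ------------------------------------------------------------ single run


def _match_abs_corr(A, B):
    """Mean |r| after optimal sign/permutation alignment of columns."""
    a = (A - A.mean(0)) / A.std(0)
    b = (B - B.mean(0)) / B.std(0)
    corr = np.abs(a.T @ b / len(a))
    rows, cols = linear_sum_assignment(-corr)
    return corr[rows, cols].mean()


def test_fastica_recovers_planted_uniform_sources():
    """Two independent uniform source vectors over 500 features, mixed into
    6 samples by a known mixing matrix, are recovered up to sign/permutation."""
    rng = np.random.default_rng(3)
    p, n = 500, 6
    S = rng.uniform(-1, 1, size=(p, 2))  # independent sub-Gaussian sources
    A = rng.normal(size=(n, 2))  # per-sample mixing weights
    X = _frame(A @ S.T)  # samples x features
    run = fastica_run(X, q=2, seed=0)
    assert _match_abs_corr(run["sources"], S) >= 0.99


def test_fastica_q_one_and_rank_guard():
    rng = np.random.default_rng(0)
    m = _frame(rng.normal(size=(10, 40)))
    run = fastica_run(m, q=1, seed=1)
    assert run["sources"].shape == (40, 1)
    with pytest.raises(ValueError):
        fastica_run(m, q=11, seed=1)


def test_fastica_seed_determinism_and_indeterminacy():
    cfg = SimulationConfig(
        seed=6, n_features_hd4=100, n_features_clp=100, n_modules=2,
        module_size_range=(15, 20), singleton_effects={},
        batch_shift=0.0, batch_scale=0.0, noise_sd=0.15,
    )
    ds, _ = simulate_dataset(cfg)
    r1 = fastica_run(ds.abundance, q=2, seed=7)
    r2 = fastica_run(ds.abundance, q=2, seed=7)
    assert np.array_equal(r1["sources"], r2["sources"])
    r3 = fastica_run(ds.abundance, q=2, seed=8)
    # different restart: identical up to sign/permutation on separated sources
    assert _match_abs_corr(r1["sources"], r3["sources"]) >= 0.999


# -------------------------------------------------------------- consensus


@pytest.fixture(scope="module")
def module_sim():
    cfg = SimulationConfig(
        seed=5, n_features_hd4=150, n_features_clp=150, n_modules=3,
        module_size_range=(25, 35), module_group_effect=(1.0, 0.0, 0.0),
        singleton_effects={}, noise_sd=0.15,
    )
    ds, truth = simulate_dataset(cfg)
    cov = build_design(ds.samples).drop(columns=["const", "group"])
    adjusted, _ = combat_adjust(ds.abundance, ds.samples["subsample"], covariates=cov)
    return ds, truth, adjusted


def test_consensus_retains_planted_modules(module_sim):
    ds, truth, adjusted = module_sim
    dec = ConsensusICA(adjusted, n_runs=50, master_seed=0).fit()
    assert dec.q == 3
    assert len(dec.sources.columns) == 3
    assert (dec.run_support["support"] >= 0.9).all()
    modules = dec.modules()
    for mem in truth.module_members:
        s = set(mem)
        best = max(len(s & set(m)) / len(s | set(m)) for _, m in modules)
        assert best >= 0.8
    # unit-SD source columns by construction
    assert np.allclose(dec.sources.std(ddof=0), 1.0, atol=1e-8)


def test_consensus_single_run_keeps_everything(module_sim):
    _, _, adjusted = module_sim
    dec = ConsensusICA(adjusted, n_runs=1, master_seed=1).fit()
    assert (dec.run_support["support"] == 1.0).all()
    assert len(dec.sources.columns) == dec.q


def test_consensus_deterministic_and_seed_robust(module_sim):
    _, truth, adjusted = module_sim
    d1 = ConsensusICA(adjusted, n_runs=10, master_seed=3).fit()
    d2 = ConsensusICA(adjusted, n_runs=10, master_seed=3).fit()
    pd.testing.assert_frame_equal(d1.sources, d2.sources)
    d3 = ConsensusICA(adjusted, n_runs=10, master_seed=4).fit()
    m1, m3 = d1.modules(), d3.modules()
    for _, mem in m1:
        s = set(mem)
        assert max(len(s & set(m)) / len(s | set(m)) for _, m in m3) >= 0.8


# ---------------------------------------------------------------- modules


def test_module_threshold_picks_spikes(module_sim):
    _, _, adjusted = module_sim
    dec = ConsensusICA(adjusted, q=3, n_runs=1, master_seed=0).fit()
    spike = np.concatenate([[5.0, -5.0], np.linspace(-0.2, 0.2, 98)])
    spike = (spike - spike.mean()) / spike.std()
    dec.sources = pd.DataFrame(
        {"IC1": spike}, index=[f"g{i}" for i in range(100)]
    )
    mods = dec.modules()
    assert set(mods.members["IC1"]) == {"g0", "g1"}
    assert len(dec.modules(sd_multiplier=0.0).members["IC1"]) == 100


def test_gaussian_source_tail_fraction():
    rng = np.random.default_rng(0)
    fracs = []
    for _ in range(30):
        s = rng.standard_normal(4000)
        fracs.append(np.mean(np.abs((s - s.mean()) / s.std()) > 2))
    assert np.mean(fracs) == pytest.approx(0.0455, abs=0.005)


def test_trait_association_flags_shifted_module(module_sim):
    ds, truth, adjusted = module_sim
    dec = ConsensusICA(adjusted, n_runs=20, master_seed=0).fit()
    assoc = dec.trait_association(ds.samples)
    z1 = truth.latent_scores.iloc[:, 0]
    match = dec.sample_scores.apply(lambda c: abs(np.corrcoef(z1, c)[0, 1])).idxmax()
    assert assoc.loc[match, "p"] < 0.01
    assert assoc.loc[match, "significant"]


def test_trait_association_alignment_guard(module_sim):
    ds, _, adjusted = module_sim
    dec = ConsensusICA(adjusted, n_runs=5, master_seed=0).fit()
    shuffled = ds.samples.iloc[::-1]
    with pytest.raises(ValueError, match="aligned"):
        dec.trait_association(shuffled)
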