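import numpy as np
import pandas as pd
import pytest

from metabomod.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Fast study-shaped generator config: full cohort, reduced panels."""
    return SimulationConfig(
        seed=11,
        n_features_hd4=60,
        n_features_clp=60,
        n_modules=4,
        module_size_range=(6, 10),
        module_group_effect=(0.5, 0.5, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def toy_tables(tmp_path):
    """Three tiny aligned input files on disk (3 samples x 4 features)."""
    matrix = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4) / 7.0,
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        columns=["f1", "f2", "f3", "f4"],
    )
    samples = pd.DataFrame(
        {
            "group": ["case", "control", "control"],
            "age": [55.0, 52.0, 60.0],
            "race": ["caucasian", "other", "caucasian"],
            "bmi": [30.0, 28.0, 33.0],
            "subsample": ["discovery", "discovery", "replication"],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    annotation = pd.DataFrame(
        {
            "panel": ["HD4", "HD4", "CLP", "CLP"],
            "super_pathway": ["Lipid", "Lipid", "Amino Acid", "Amino Acid"],
            "sub_pathway": ["Sphingolipid", "Sphingolipid", "Lysine", "Lysine"],
        },
        index=pd.Index(["f1", "f2", "f3", "f4"], name="feature_id"),
    )
    paths = {
        "matrix": tmp_path / "abundance.tsv",
        "metadata": tmp_path / "samples.tsv",
        "annotation": tmp_path / "annotation.tsv",
    }
    matrix.to_csv(paths["matrix"], sep="\t")
    samples.to_csv(paths["metadata"], sep="\t")
    annotation.to_csv(paths["annotation"], sep="\t")
    return paths, matrix, samples, annotation
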