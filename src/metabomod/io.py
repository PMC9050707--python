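"""Reading, validating and writing the tabular formats used by the pipeline.

On-disk convention: delimited text with a header row. The abundance matrix is
samples x features with the sample id in the first column; sample metadata is
one row per sample; the feature annotation is one row per feature. Delimiter
is auto-detected from the extension (``.tsv`` tab, ``.csv`` comma); tab is the
canonical output format. Missing values may be written as an empty field or
``NA`` and are always emitted as ``NA``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "load_dataset",
    "write_table",
    "split_subsamples",
    "validate_samples",
    "validate_annotation",
]

GROUPS = ("case", "control")
SUBSAMPLES = ("discovery", "replication")

#: metadata columns every analysis stage relies on
REQUIRED_SAMPLE_COLUMNS = ("group", "age", "race", "bmi", "subsample")
REQUIRED_ANNOTATION_COLUMNS = ("panel", "super_pathway", "sub_pathway")


class FormatError(ValueError):
    """A required column or header is missing from an input table."""


class AlignmentError(ValueError):
    """Sample or feature identifiers do not line up across input tables."""


@dataclass
class Dataset:
    """Aligned abundance matrix, sample metadata and feature annotation.

    ``abundance`` is samples x features (rows indexed by sample_id, columns
    by feature_id); ``samples`` is indexed by sample_id; ``annotation`` is
    indexed by feature_id, in the same order as the matrix columns.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.samples.index):
            raise AlignmentError("abundance rows and sample table are not aligned")
        if not self.abundance.columns.equals(self.annotation.index):
            raise AlignmentError("abundance columns and annotation are not aligned")
        validate_samples(self.samples)
        validate_annotation(self.annotation)

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundance.shape[1]

    def subset_samples(self, sample_ids) -> "Dataset":
        sample_ids = list(sample_ids)
        return replace(
            self,
            abundance=self.abundance.loc[sample_ids],
            samples=self.samples.loc[sample_ids],
        )

    def panel(self, name: str) -> list[str]:
        """Feature ids belonging to one annotation panel."""
        mask = self.annotation["panel"] == name
        if not mask.any():
            raise ValueError(f"no features in panel {name!r}")
        return list(self.annotation.index[mask])


def validate_samples(samples: pd.DataFrame) -> None:
    if samples.index.has_duplicates:
        dups = samples.index[samples.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dups}")
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"sample table missing required columns: {missing}")
    bad_group = set(samples["group"].unique()) - set(GROUPS)
    if bad_group:
        raise FormatError(f"unknown group labels: {sorted(bad_group)}")
    bad_sub = set(samples["subsample"].unique()) - set(SUBSAMPLES)
    if bad_sub:
        raise FormatError(f"unknown subsample labels: {sorted(bad_sub)}")
    if (samples["age"] <= 0).any() or (samples["bmi"] <= 0).any():
        raise FormatError("age and bmi must be positive")
    if "pcl_total" in samples.columns:
        pcl = samples["pcl_total"].dropna()
        if ((pcl < 17) | (pcl > 85)).any():
            raise FormatError("pcl_total must lie within 17..85")


def validate_annotation(annotation: pd.DataFrame) -> None:
    if annotation.index.has_duplicates:
        dups = annotation.index[annotation.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate feature ids: {dups}")
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise FormatError(f"annotation missing required columns: {missing}")
    if annotation["panel"].isna().any() or (annotation["panel"] == "").any():
        raise FormatError("every feature needs a non-empty panel label")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read(path: Path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), na_values=["NA", ""], keep_default_na=True)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a header plus at least one data column")
    first = df.columns[0]
    if first.lower() not in (index_name, index_name.lower()):
        # accept any first-column name but record the convention mismatch
        warnings.warn(
            f"{path}: first column named {first!r}, expected {index_name!r}; "
            "using it as the index",
            stacklevel=2,
        )
    df = df.set_index(first)
    df.index = df.index.astype(str)
    df.index.name = index_name
    return df


def load_dataset(
    matrix_path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path,
) -> Dataset:
    """Load and align the three pipeline inputs.

    Samples are aligned by id between matrix and metadata, and features
    between matrix and annotation; any identifier present in the matrix but
    absent from its companion table raises :class:`AlignmentError` naming the
    offenders.
    """
    matrix = _read(Path(matrix_path), "sample_id").astype(float)
    samples = _read(Path(metadata_path), "sample_id")
    annotation = _read(Path(annotation_path), "feature_id")

    missing_samples = matrix.index.difference(samples.index).tolist()
    if missing_samples:
        raise AlignmentError(
            f"samples in matrix but not in metadata: {missing_samples}"
        )
    missing_features = matrix.columns.difference(annotation.index).tolist()
    if missing_features:
        raise AlignmentError(
            f"features in matrix but not in annotation: {missing_features}"
        )
    extra = samples.index.difference(matrix.index).tolist()
    if extra:
        warnings.warn(f"metadata rows without matrix samples dropped: {extra}", stacklevel=2)
    samples = samples.loc[matrix.index]
    annotation = annotation.loc[matrix.columns]
    return Dataset(abundance=matrix, samples=samples, annotation=annotation)


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    sort_by: str | list[str] | None = None,
    float_digits: int = 6,
) -> Path:
    """Write a results table as deterministic TSV.

    Floats are formatted at ``float_digits`` significant digits and missing
    values as ``NA``; with ``sort_by`` the rows are sorted (stable, ties kept
    in input order) so repeated runs produce byte-identical files.
    """
    if table.shape[0] == 0:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    out = table.sort_values(sort_by, kind="stable") if sort_by else table
    out.to_csv(
        path,
        sep="\t",
        na_rep="NA",
        float_format=f"%.{float_digits}g",
        index=out.index.name is not None,
    )
    return path


def split_subsamples(dataset: Dataset) -> tuple[Dataset, Dataset]:
    """Partition a dataset into its discovery and replication subsamples."""
    labels = dataset.samples["subsample"]
    unknown = set(labels.unique()) - set(SUBSAMPLES)
    if unknown:
        raise ValueError(f"unknown subsample labels: {sorted(unknown)}")
    disc_ids = dataset.samples.index[labels == "discovery"]
    rep_ids = dataset.samples.index[labels == "replication"]
    if len(rep_ids) == 0:
        warnings.warn("replication subsample is empty", stacklevel=2)
    if len(disc_ids) == 0:
        warnings.warn("discovery subsample is empty", stacklevel=2)
    return dataset.subset_samples(disc_ids), dataset.subset_samples(rep_ids)
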