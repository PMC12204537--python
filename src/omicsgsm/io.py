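"""Ingestion, validation and sample handling for the three omics layers.

Matrices are features x samples: first column feature ids, header row
sample ids, TSV or CSV.  Labels are a two-column table (sample_id,
class) with exactly two classes.  Class balancing (majority-class
downsampling to a 1:1 ratio) and the stratified 90/10 outer split live
here because every outer iteration of the pipeline starts with them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("mRNA", "miRNA", "CpG")


@dataclass
class OmicsMatrix:
    """One omics layer: a real-valued features x samples matrix.

    Parameters
    ----------
    kind:
        One of ``mRNA``, ``miRNA``, ``CpG``.
    data:
        DataFrame indexed by feature id with sample ids as columns.
        Values are expression levels or methylation beta values.
    """

    kind: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}; expected one of {FEATURE_KINDS}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r} in {self.kind} matrix")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in {self.kind} matrix")
        if not np.isfinite(self.data.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.data.to_numpy()))[0]
            raise ValueError(
                f"non-finite value in {self.kind} matrix at feature "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def restrict_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        """Return a copy restricted to ``sample_ids`` in the given order."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from {self.kind} matrix: {missing[:5]}")
        return OmicsMatrix(self.kind, self.data.loc[:, sample_ids])


@dataclass
class SampleLabels:
    """Binary class labels keyed by sample id."""

    labels: pd.Series

    def __post_init__(self) -> None:
        if self.labels.index.duplicated().any():
            dup = self.labels.index[self.labels.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in labels")
        classes = sorted(self.labels.unique())
        if len(classes) != 2:
            raise ValueError(f"expected exactly 2 classes, found {len(classes)}: {classes}")

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def restrict(self, sample_ids: list[str]) -> "SampleLabels":
        return SampleLabels(self.labels.loc[sample_ids])

    def class_counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with their defaults.

    ``master_seed`` is the single entropy source: iteration ``i`` uses
    seed ``(master_seed + i) mod 2**31`` so any iteration is replayable
    on its own.
    """

    k_top_features: int = 10
    n_outer_iterations: int = 10
    n_internal_splits: int = 10
    internal_test_fraction: float = 0.1
    outer_test_fraction: float = 0.1
    n_top_progroups: int = 10
    correlation_method: str = "spearman"
    correlation_threshold: float = 0.5
    require_negative_mirna: bool = False
    merge_mode: str = "identical"
    jaccard_threshold: float = 0.5
    n_trees: int = 100
    master_seed: int = 0
    positive_class: str | None = None

    def __post_init__(self) -> None:
        for name in ("k_top_features", "n_outer_iterations", "n_internal_splits",
                     "n_top_progroups", "n_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("internal_test_fraction", "outer_test_fraction", "jaccard_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError(f"correlation_method must be pearson or spearman, got {self.correlation_method!r}")
        if self.merge_mode not in ("identical", "jaccard"):
            raise ValueError(f"merge_mode must be identical or jaccard, got {self.merge_mode!r}")

    def iteration_seed(self, iteration: int) -> int:
        return (self.master_seed + iteration) % (2**31)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})


def read_omics_matrix(path: str | Path, feature_kind: str) -> OmicsMatrix:
    """Read a delimited features x samples matrix.

    Rows containing missing values are dropped (a count is logged); any
    other non-numeric cell is a hard error naming its location.  Row and
    column order are preserved as in the file.
    """
    df = _read_table(path)
    if df.shape[1] == 0:
        raise ValueError(f"no sample columns in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    # distinguish cells that failed to parse from cells missing in the file
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r} in {path}"
        )
    has_missing = numeric.isna().any(axis=1)
    if has_missing.any():
        logger.warning("dropping %d rows with missing values from %s", int(has_missing.sum()), path)
        numeric = numeric.loc[~has_missing]
    if numeric.index.duplicated().any():
        dup = numeric.index[numeric.index.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r} in {path}")
    return OmicsMatrix(feature_kind, numeric.astype(float))


def read_labels(path: str | Path) -> SampleLabels:
    """Read a two-column (sample_id, class) table."""
    df = _read_table(path)
    if df.shape[1] != 1:
        raise ValueError(f"label file must have exactly two columns (sample_id, class): {path}")
    return SampleLabels(df.iloc[:, 0].astype(str))


def harmonize_samples(
    matrices: tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix],
    labels: SampleLabels,
) -> tuple[tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix], SampleLabels]:
    """Restrict all layers and labels to their common samples.

    Sample order in the output is the order of the common samples in the
    first matrix, identical across all layers.  Idempotent.
    """
    common = set(labels.sample_ids)
    for m in matrices:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("no samples shared by all three omics layers and the labels")
    ordered = [s for s in matrices[0].sample_ids if s in common]
    out = tuple(m.restrict_samples(ordered) for m in matrices)
    return out, labels.restrict(ordered)


def downsample_balanced(labels: SampleLabels, seed: int) -> SampleLabels:
    """Downsample the majority class to the minority class size (1:1).

    The minority class is kept intact; the majority subset is drawn
    uniformly without replacement from ``seed``.
    """
    counts = labels.class_counts()
    if min(counts.values()) == 0:
        raise ValueError("a class has zero samples")
    minority = min(counts, key=lambda c: (counts[c], c))
    n_keep = counts[minority]
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    for cls in labels.classes:
        ids = [s for s in labels.sample_ids if labels.labels[s] == cls]
        if len(ids) > n_keep:
            ids = sorted(rng.choice(ids, size=n_keep, replace=False))
        kept.extend(ids)
    kept = [s for s in labels.sample_ids if s in set(kept)]  # preserve input order
    return labels.restrict(kept)


def outer_split(
    labels: SampleLabels, test_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Stratified outer train/test split.

    Per class the test count is ``round(n * test_fraction)`` with a
    minimum of 1.  Returns (train_ids, test_ids), disjoint and jointly
    exhaustive, each in input sample order.
    """
    rng = np.random.default_rng(seed)
    test: set[str] = set()
    for cls in labels.classes:
        ids = [s for s in labels.sample_ids if labels.labels[s] == cls]
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples; cannot stratify")
        n_test = max(1, round(len(ids) * test_fraction))
        test.update(rng.choice(ids, size=n_test, replace=False))
    train_ids = [s for s in labels.sample_ids if s not in test]
    test_ids = [s for s in labels.sample_ids if s in test]
    return train_ids, test_ids
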