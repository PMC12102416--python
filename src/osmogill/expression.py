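"""Expression-matrix containers, I/O, normalization and ortholog pairing.

The substrate of the whole pipeline is a gene x sample abundance matrix with
per-sample metadata (tissue, species, replicate).  Values enter on an
arbitrary non-negative raw scale (expected counts, FPKM, ...), are
log2(N+1)-transformed and quantile-normalized across samples, and are then
summarized to per-tissue means for the tissue-specificity index.

Two species' matrices are joined over a one-to-one ortholog table so that
row k of one matrix corresponds to row k of the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: The five tissues of the two-species talitrid design.
TISSUES = ("antennae", "compound_eyes", "gills", "nerve", "pereopods")

METADATA_COLUMNS = ("tissue", "species", "replicate")


class ValidationError(ValueError):
    """Raised when an input matrix, metadata table or parameter is invalid."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in labels:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionDataset:
    """A validated gene x sample expression matrix plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    metadata
        DataFrame indexed by sample id with at least columns
        ``tissue``, ``species``, ``replicate``; an optional ``batch``
        column is carried along but ignored by all computation.
    scale
        ``"raw"`` for non-negative upstream abundances, ``"log"`` after
        :func:`log_transform`.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log"):
            raise ValidationError(f"scale must be 'raw' or 'log', got {self.scale!r}")
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValidationError(
                f"sample missing from metadata: {missing[0]!r}"
            )
        # harmonize: metadata rows in matrix column order
        self.metadata = self.metadata.loc[list(self.values.columns)]
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValidationError(f"metadata lacks required column {col!r}")
        if self.metadata["tissue"].isna().any():
            bad = self.metadata.index[self.metadata["tissue"].isna()][0]
            raise ValidationError(f"sample {bad!r} has no tissue label")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if self.scale == "raw" and (arr < 0).any():
            g = self.values.index[np.where(arr < 0)[0][0]]
            raise ValidationError(f"negative raw expression value for gene {g!r}")
        if "batch" in self.metadata.columns:
            logger.info(
                "metadata carries a batch column (%d levels); it is ignored by "
                "all computation in this package",
                self.metadata["batch"].nunique(),
            )

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in order of first appearance."""
        return list(dict.fromkeys(self.metadata["tissue"]))

    def samples_of_tissue(self, tissue: str) -> list[str]:
        m = self.metadata["tissue"] == tissue
        return list(self.metadata.index[m])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        return replace(self, values=self.values.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionDataset":
        return ExpressionDataset(
            values=self.values[list(samples)],
            metadata=self.metadata.loc[list(samples)],
            scale=self.scale,
        )

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, matrix_path: str | Path, metadata_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene")
        self.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


@dataclass
class TissueProfile:
    """Per-gene mean expression across tissues (genes x tissues)."""

    means: pd.DataFrame

    def __post_init__(self) -> None:
        if self.means.shape[1] < 2:
            raise ValidationError("tissue profile needs at least 2 tissues")
        arr = self.means.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("tissue means must be finite")
        if (arr < 0).any():
            raise ValidationError("tissue means must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.means.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.means.columns)

    @property
    def n_tissues(self) -> int:
        return self.means.shape[1]


@dataclass
class OrthologTable:
    """One-to-one ortholog pairs between two species' gene identifiers."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        _check_unique([a for a, _ in self.pairs], "ortholog (left)")
        _check_unique([b for _, b in self.pairs], "ortholog (right)")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.shape[1] != 2:
            raise ValidationError(
                f"ortholog table must have exactly 2 columns, got {df.shape[1]}"
            )
        return cls(list(df.itertuples(index=False, name=None)))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.pairs).to_csv(path, sep="\t", header=False, index=False)

    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


# -- operations -----------------------------------------------------------


def load_dataset(
    matrix_path: str | Path,
    metadata_path: str | Path,
    scale: str = "raw",
) -> ExpressionDataset:
    """Read a TSV expression matrix (header = sample ids, column 1 = gene
    ids) and a metadata TSV (columns sample_id, tissue, species, replicate,
    optionally batch) into a validated :class:`ExpressionDataset`."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    dup = values.index[values.index.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate gene identifier: {dup[0]!r}")
    metadata = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in metadata.columns:
        raise ValidationError("metadata must have a sample_id column")
    metadata = metadata.set_index("sample_id")
    return ExpressionDataset(values=values, metadata=metadata, scale=scale)


def log_transform(ds: ExpressionDataset) -> ExpressionDataset:
    """Replace every abundance v by log2(v + 1).

    Base 2 keeps the transformed scale commensurate with the |log2FC| >= 1
    differential-expression threshold used downstream.
    """
    if ds.scale == "log":
        raise ValidationError("dataset already log-scaled (double transform)")
    values = np.log2(ds.values.astype(float) + 1.0)
    return ExpressionDataset(values=values, metadata=ds.metadata.copy(), scale="log")


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalize columns so every sample shares one distribution.

    The target distribution is the across-sample mean of the column-sorted
    values (rank means).  Each value is replaced by the target value at its
    within-column rank; ties receive the mean of the rank-mean values for
    their tied ranks, so the operation is idempotent.
    """
    if ds.n_samples < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    arr = ds.values.to_numpy(dtype=float)
    n = arr.shape[0]
    target = np.sort(arr, axis=0).mean(axis=1)
    ranks = rankdata(arr, axis=0, method="average")
    normalized = np.interp(ranks, np.arange(1, n + 1), target)
    values = pd.DataFrame(normalized, index=ds.values.index, columns=ds.values.columns)
    return ExpressionDataset(values=values, metadata=ds.metadata.copy(), scale=ds.scale)


def tissue_means(ds: ExpressionDataset) -> TissueProfile:
    """Arithmetic mean over the replicate samples of each tissue."""
    if ds.n_genes == 0 or ds.n_samples == 0:
        raise ValidationError("cannot summarize an empty dataset")
    groups = {t: ds.samples_of_tissue(t) for t in ds.tissues}
    means = pd.DataFrame(
        {t: ds.values[s].mean(axis=1) for t, s in groups.items()},
        index=ds.values.index,
    )
    # log-scale values can be mathematically negative only if raw inputs were
    # invalid; clip exact floating noise at zero
    means[means < 0] = 0.0
    return TissueProfile(means=means)


def pair_orthologs(
    dsA: ExpressionDataset,
    dsB: ExpressionDataset,
    orth: OrthologTable,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict and order both datasets to the shared one-to-one ortholog
    pairs, so row k of A corresponds to row k of B."""
    genesA = set(dsA.genes)
    genesB = set(dsB.genes)
    kept = [(a, b) for a, b in orth.pairs if a in genesA and b in genesB]
    if not kept:
        raise ValidationError("no ortholog pair overlaps both datasets")
    outA = dsA.subset_genes([a for a, _ in kept])
    outB = dsB.subset_genes([b for _, b in kept])
    return outA, outB
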