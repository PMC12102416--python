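"""Tissue-specificity index tau and specifically-expressed gene calling.

For a gene with mean expression X_i in each of n tissues,

    tau = sum_i (1 - x_i) / (n - 1),   x_i = X_i / max_i X_i

tau ranges from 0 (uniform expression) to 1 (expression confined to a
single tissue).  A gene is called specifically expressed in a tissue when
tau exceeds a threshold (default 0.9), the tissue holds the unique maximum
mean, and the replicate-consistency rule holds: the top r samples by
expression (r = replicate count of the top tissue) all come from that
tissue.  Genes with zero expression everywhere have undefined tau and are
excluded from calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionDataset, OrthologTable, TissueProfile, ValidationError


@dataclass
class TauResult:
    """Per-gene tau and the supporting quantities for the specificity call."""

    gene: str
    tau: float | None
    x_hat: np.ndarray | None
    top_tissue: str | None
    replicate_consistent: bool | None
    specific_in: str | None = None


def tau_from_means(means: np.ndarray) -> np.ndarray:
    """Vectorized tau over a genes x tissues array of non-negative means.

    Returns NaN for all-zero rows (tau undefined).
    """
    means = np.asarray(means, dtype=float)
    if means.ndim == 1:
        means = means[None, :]
    n = means.shape[1]
    if n < 2:
        raise ValidationError("tau requires at least 2 tissues")
    if (means < 0).any():
        raise ValidationError("tau requires non-negative expression values")
    mx = means.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x_hat = means / mx[:, None]
        tau = (1.0 - x_hat).sum(axis=1) / (n - 1)
    tau[mx == 0] = np.nan
    return tau


def compute_tau(
    profile: TissueProfile,
    gene: str,
    ds: ExpressionDataset | None = None,
) -> TauResult:
    """Tau for a single gene of a tissue profile.

    When the per-sample dataset ``ds`` is supplied the replicate-consistency
    flag is evaluated as well.
    """
    row = profile.means.loc[gene].to_numpy(dtype=float)
    tau = float(tau_from_means(row)[0])
    if np.isnan(tau):
        return TauResult(gene, None, None, None, None)
    x_hat = row / row.max()
    order = np.argsort(-row, kind="stable")
    top = profile.tissues[order[0]]
    tie = int((row == row.max()).sum()) > 1
    consistent = None
    if ds is not None:
        consistent = _replicate_consistent(ds, gene, top)
    return TauResult(
        gene=gene,
        tau=tau,
        x_hat=x_hat,
        top_tissue=None if tie else top,
        replicate_consistent=consistent,
    )


def _replicate_consistent(ds: ExpressionDataset, gene: str, top_tissue: str) -> bool:
    """True iff the top r samples for this gene (r = replicate count of
    ``top_tissue``) all carry the ``top_tissue`` label."""
    vals = ds.values.loc[gene].to_numpy(dtype=float)
    tissues = ds.metadata["tissue"].to_numpy()
    r = int((tissues == top_tissue).sum())
    order = np.argsort(-vals, kind="stable")
    return bool((tissues[order[:r]] == top_tissue).all())


def tau_table(profile: TissueProfile, ds: ExpressionDataset | None = None) -> pd.DataFrame:
    """Whole-profile tau table (gene, tau, top_tissue, replicate_consistent).

    ``top_tissue`` is empty for all-zero genes and for max ties;
    ``replicate_consistent`` is evaluated only when ``ds`` is given.
    """
    arr = profile.means.to_numpy(dtype=float)
    taus = tau_from_means(arr)
    mx = arr.max(axis=1)
    tissues = np.array(profile.tissues)
    top_idx = arr.argmax(axis=1)
    tie = (arr == mx[:, None]).sum(axis=1) > 1
    top = np.where((mx > 0) & ~tie, tissues[top_idx], "")

    consistent = np.full(len(taus), False)
    if ds is not None:
        vals = ds.values.loc[profile.genes].to_numpy(dtype=float)
        sample_tissue = ds.metadata["tissue"].to_numpy()
        counts = {t: int((sample_tissue == t).sum()) for t in profile.tissues}
        order = np.argsort(-vals, axis=1, kind="stable")
        for i, t in enumerate(top):
            if not t:
                continue
            r = counts[t]
            consistent[i] = bool((sample_tissue[order[i, :r]] == t).all())
    return pd.DataFrame(
        {
            "gene": profile.genes,
            "tau": taus,
            "top_tissue": top,
            "replicate_consistent": consistent,
        }
    ).set_index("gene")


def call_specific_genes(
    taus: pd.DataFrame,
    ds: ExpressionDataset,
    threshold: float = 0.9,
) -> dict[str, set[str]]:
    """Per-tissue sets of specifically expressed genes.

    A gene is assigned to its (unique) top tissue iff tau > ``threshold``
    and the replicate-consistency rule holds; each gene lands in at most
    one tissue.  ``taus`` is the output of :func:`tau_table` computed with
    the same dataset.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"tau threshold must lie in (0,1), got {threshold}")
    sets: dict[str, set[str]] = {t: set() for t in ds.tissues}
    called = taus[
        (taus["tau"] > threshold)
        & (taus["top_tissue"] != "")
        & taus["replicate_consistent"]
    ]
    for gene, row in called.iterrows():
        sets[row["top_tissue"]].add(gene)
    return sets


def common_specific_genes(
    setsA: dict[str, set[str]],
    setsB: dict[str, set[str]],
    orth: OrthologTable,
    tissue: str,
) -> set[tuple[str, str]]:
    """Ortholog pairs specifically expressed in ``tissue`` of BOTH species."""
    if tissue not in setsA:
        raise ValidationError(f"tissue {tissue!r} absent in species A calls")
    if tissue not in setsB:
        raise ValidationError(f"tissue {tissue!r} absent in species B calls")
    b_set = setsB[tissue]
    return {
        (a, b)
        for a, b in orth.pairs
        if a in setsA[tissue] and b in b_set
    }
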