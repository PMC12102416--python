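"""Co-expression module summaries, module merging, hub genes and TOM edges.

Module discovery itself (soft-threshold selection, dynamic tree cut) is out
of scope: assignments arrive from upstream network analysis or from the
synthetic generator's ground truth.  What is computed here is the module
machinery the downstream claims rest on:

* the module eigengene — first principal component of the module's
  standardized gene x sample submatrix, sign-oriented so members correlate
  positively with it on average;
* average-linkage merging of modules whose eigengene dissimilarity
  (1 - correlation) falls below a height cutoff (default 0.2);
* Pearson module-trait correlations with Student-t p-values;
* per-gene module membership MM (correlation with the own-module
  eigengene) and gene significance GS (correlation with a trait
  indicator), with the hub rule MM > 0.8 and |GS| > 0.2;
* an unsigned topological-overlap (TOM) edge list thresholded at an export
  weight (default 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .expression import ExpressionDataset, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ModuleAssignment:
    """Gene -> module label mapping with a minimum module size."""

    labels: dict[str, str]
    min_size: int = 100

    def __post_init__(self) -> None:
        if any(not m for m in self.labels.values()):
            raise ValidationError("module labels must be non-empty")
        sizes = self.sizes()
        small = [m for m, n in sizes.items() if n < self.min_size]
        if small:
            raise ValidationError(
                f"module {small[0]!r} has {sizes[small[0]]} genes "
                f"(< min size {self.min_size})"
            )

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.labels.values():
            out[m] = out.get(m, 0) + 1
        return out

    def modules(self) -> list[str]:
        return sorted(self.sizes())

    def genes_of(self, module: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]

    @classmethod
    def from_tsv(cls, path: str | Path, min_size: int = 100) -> "ModuleAssignment":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "module"], dtype=str)
        return cls(dict(df.itertuples(index=False)), min_size=min_size)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(sorted(self.labels.items())).to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class EigengeneMatrix:
    """Module x sample eigengene matrix with explained-variance fractions."""

    eigengenes: pd.DataFrame  # modules x samples, unit-norm rows
    explained_variance: pd.Series  # per module, fraction of module variance


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValidationError("zero-variance gene in module submatrix")
    return (x - mu) / sd


def module_eigengene(ds: ExpressionDataset, assign: ModuleAssignment) -> EigengeneMatrix:
    """First principal component of each module's standardized submatrix.

    The eigengene has unit norm over samples and is oriented so that the
    mean correlation with the module's member genes is non-negative.
    """
    if ds.scale != "log":
        raise ValidationError("eigengenes expect log-scale data")
    missing = [g for g in assign.labels if g not in ds.values.index]
    if missing:
        raise ValidationError(f"assigned gene {missing[0]!r} absent from dataset")
    rows = {}
    ev = {}
    for module in assign.modules():
        genes = assign.genes_of(module)
        if len(genes) < 2:
            raise ValidationError(f"module {module!r} has fewer than 2 genes")
        x = _standardize_rows(ds.values.loc[genes].to_numpy(dtype=float))
        # right singular vector across samples = principal scores
        _, s, vt = np.linalg.svd(x, full_matrices=False)
        e = vt[0]
        if (x @ e).mean() < 0:
            e = -e
        rows[module] = e
        ev[module] = float(s[0] ** 2 / (s**2).sum())
    eig = pd.DataFrame(rows, index=ds.samples).T
    return EigengeneMatrix(eigengenes=eig, explained_variance=pd.Series(ev))


def merge_close_modules(
    ds: ExpressionDataset,
    assign: ModuleAssignment,
    height_cutoff: float = 0.2,
) -> ModuleAssignment:
    """Merge modules whose eigengene dissimilarity (1 - Pearson r) falls
    below ``height_cutoff`` under average-linkage clustering; recompute
    eigengenes and repeat until the module count is stable.

    The merged module keeps the label of its largest constituent.
    """
    if not (0.0 < height_cutoff < 1.0):
        raise ValidationError(f"height cutoff must lie in (0,1), got {height_cutoff}")
    labels = dict(assign.labels)
    while True:
        current = ModuleAssignment(labels, min_size=assign.min_size)
        modules = current.modules()
        if len(modules) < 2:
            return current
        eig = module_eigengene(ds, current).eigengenes.loc[modules]
        corr = np.corrcoef(eig.to_numpy())
        dissim = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dissim, 0.0)
        z = linkage(squareform(dissim, checks=False), method="average")
        clusters = fcluster(z, t=height_cutoff, criterion="distance")
        if len(set(clusters)) == len(modules):
            return current
        sizes = current.sizes()
        for cid in set(clusters):
            members = [m for m, c in zip(modules, clusters) if c == cid]
            keep = max(members, key=lambda m: (sizes[m], m))
            for m in members:
                if m != keep:
                    for g, lab in labels.items():
                        if lab == m:
                            labels[g] = keep


def module_trait_correlation(
    eig: EigengeneMatrix,
    traits: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided Student-t p for every module x trait pair.

    ``traits`` is a sample x trait numeric matrix (tissue one-hot
    indicators by default; see :func:`tissue_trait_matrix`).
    """
    e = eig.eigengenes
    t = traits.loc[e.columns]
    const = [c for c in t.columns if t[c].nunique() <= 1]
    if const:
        raise ValidationError(f"trait column {const[0]!r} is constant")
    m = e.shape[1]
    ez = _standardize_rows(e.to_numpy(dtype=float))
    tz = _standardize_rows(t.to_numpy(dtype=float).T)
    r = (ez @ tz.T) / m
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((m - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=m - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    idx, cols = e.index, t.columns
    return (
        pd.DataFrame(r, index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
    )


def tissue_trait_matrix(ds: ExpressionDataset, include_species: bool = False) -> pd.DataFrame:
    """Sample x trait one-hot tissue indicators (optionally + species)."""
    out = pd.get_dummies(ds.metadata["tissue"]).astype(float)
    if include_species:
        sp = pd.get_dummies(ds.metadata["species"]).astype(float)
        if sp.shape[1] == 2:
            sp = sp.iloc[:, :1]
        out = pd.concat([out, sp], axis=1)
    return out


def membership_and_significance(
    ds: ExpressionDataset,
    assign: ModuleAssignment,
    eig: EigengeneMatrix,
    traits: pd.DataFrame,
    target_trait: str,
) -> pd.DataFrame:
    """Per-gene MM and GS for a target trait.

    MM(g) = Pearson r between the gene's expression and its own module's
    eigengene; GS(g) = Pearson r between the gene's expression and the
    target trait indicator.  Zero-variance genes get NaN and a flag.
    """
    if target_trait not in traits.columns:
        raise ValidationError(f"unknown trait {target_trait!r}")
    genes = [g for g in ds.genes if g in assign.labels]
    x = ds.values.loc[genes, :].to_numpy(dtype=float)
    m = x.shape[1]
    sd = x.std(axis=1)
    undefined = sd == 0
    if undefined.any():
        logger.warning("%d zero-variance genes have undefined MM/GS", int(undefined.sum()))
    xz = np.zeros_like(x)
    ok = ~undefined
    xz[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    e = eig.eigengenes.loc[:, ds.samples]
    ez = _standardize_rows(e.to_numpy(dtype=float))
    trait = traits.loc[ds.samples, target_trait].to_numpy(dtype=float)
    tz = (trait - trait.mean()) / trait.std()
    module_of = np.array([assign.labels[g] for g in genes])
    mod_index = {mname: i for i, mname in enumerate(e.index)}
    mm = np.einsum("ij,ij->i", xz, ez[[mod_index[mo] for mo in module_of]]) / m
    gs = (xz @ tz) / m
    mm[undefined] = np.nan
    gs[undefined] = np.nan
    return pd.DataFrame(
        {
            "module": module_of,
            "MM": np.clip(mm, -1, 1),
            "GS": np.clip(gs, -1, 1),
            "undefined": undefined,
        },
        index=pd.Index(genes, name="gene"),
    )


def select_hub_genes(
    report: pd.DataFrame,
    mm_threshold: float = 0.8,
    gs_threshold: float = 0.2,
) -> pd.DataFrame:
    """Flag hub genes: MM > mm_threshold AND |GS| > gs_threshold."""
    for name, v in (("MM", mm_threshold), ("GS", gs_threshold)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} threshold must lie in [0,1], got {v}")
    out = report.copy()
    out["hub"] = (out["MM"] > mm_threshold) & (out["GS"].abs() > gs_threshold)
    out.loc[out["undefined"], "hub"] = False
    return out


def adjacency_matrix(ds: ExpressionDataset, genes, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-power adjacency a_ij = |cor(x_i, x_j)|^beta over a
    gene subset (zero diagonal); zero-variance genes are excluded with a
    warning."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValidationError("network construction needs at least 2 genes")
    x = ds.values.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        dropped = [g for g, s in zip(genes, sd) if s == 0]
        logger.warning("excluding %d zero-variance genes from the network", len(dropped))
        genes = [g for g, s in zip(genes, sd) if s > 0]
        if len(genes) < 2:
            raise ValidationError("fewer than 2 genes with variance")
        x = ds.values.loc[genes].to_numpy(dtype=float)
    a = np.abs(np.corrcoef(x)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=genes, columns=genes)


def tom_matrix(ds: ExpressionDataset, genes, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned topological overlap matrix over a gene subset.

    Adjacency a_ij = |cor(x_i, x_j)|^beta (zero diagonal);
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the connectivity sum_u a_iu.
    """
    adj = adjacency_matrix(ds, genes, beta=beta)
    genes = list(adj.index)
    a = adj.to_numpy()
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(np.clip(tom, 0.0, 1.0), index=genes, columns=genes)


def tom_edge_list(
    ds: ExpressionDataset,
    genes,
    beta: float = 6.0,
    weight_cutoff: float = 0.3,
    use_tom: bool = True,
) -> pd.DataFrame:
    """Symmetric network edges with weight >= ``weight_cutoff`` (no self
    edges), as a Cytoscape-ready (source, target, weight) table.

    The weight is the topological overlap by default; ``use_tom=False``
    exports the raw soft-power adjacency |cor|^beta instead.
    """
    if use_tom:
        tom = tom_matrix(ds, genes, beta=beta)
    else:
        tom = adjacency_matrix(ds, genes, beta=beta)
    names = list(tom.index)
    arr = tom.to_numpy()
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if arr[i, j] >= weight_cutoff:
                rows.append((names[i], names[j], arr[i, j]))
    return pd.DataFrame(rows, columns=["source", "target", "weight"])
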