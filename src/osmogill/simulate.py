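"""Seed-reproducible synthetic data with the structure the analysis assumes.

The generator emulates a two-species, five-tissue (antennae, compound eyes,
gills, nerve, pereopods), ~3-replicate bulk RNA-seq design over ~10,000
ortholog-paired genes, with

* planted tissue-specific genes: off outside their tissue (half-normal
  leak around zero on the log2 scale) and expressed ``effect_log2`` above
  the leak level inside it — the standard notion of a tissue-specific
  gene, and the regime in which a tau > 0.9 call is meaningful;
* planted gill-differential genes: an ordinary baseline everywhere plus a
  signed log2 shift in the gill samples only;
* planted co-expression modules: shared tissue-level latent factors with
  per-gene loadings; the first module's factor is the gill indicator, so
  it is the trait-coupled module;
* a synthetic GO ontology (random rooted DAG, is_a/part_of edges) with
  per-tissue term clusters and gene annotations drawn coherently from a
  gene's home cluster.

Log-normal expression is used rather than negative-binomial counts because
every downstream statistic operates on the normalized log scale; a
Poisson count-emitting mode is available for realism checks.  All outputs
are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .expression import (
    TISSUES,
    ExpressionDataset,
    OrthologTable,
    ValidationError,
)
from .ontology import AnnotationMap, OntologyDAG, TermRecord

#: log2-scale sd of the half-normal leak of an off-state gene
OFF_LEAK_SD = 0.1


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset (or a two-species pair)."""

    specific: dict[str, list[str]] = field(default_factory=dict)
    de_up: list[str] = field(default_factory=list)
    de_down: list[str] = field(default_factory=list)
    modules: dict[str, list[str]] = field(default_factory=dict)
    gill_module: str | None = None
    #: two-species extensions (empty for a single species)
    specific_b: dict[str, list[str]] = field(default_factory=dict)
    species_de_up_a: list[str] = field(default_factory=list)
    species_de_up_b: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# expression


def _gene_ids(n: int, prefix: str) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


@dataclass
class _GenePlan:
    """Species-independent blueprint: per-gene role and parameters."""

    n_genes: int
    tissues: tuple[str, ...]
    specific_idx: dict[str, np.ndarray]     # tissue -> gene indices
    specific_level: np.ndarray              # expressed level of specific genes
    de_idx_up: np.ndarray
    de_idx_down: np.ndarray
    de_mu: np.ndarray                       # baseline of all genes
    module_idx: dict[str, np.ndarray]
    module_factor: dict[str, np.ndarray]    # per-tissue latent factor values
    gill_module: str


def _make_plan(
    rng: np.random.Generator,
    n_genes: int,
    tissues: tuple[str, ...],
    specific_fraction: float,
    de_fraction: float,
    n_modules: int,
    module_size: int,
    effect_log2: float,
    gill_tissue: str,
) -> _GenePlan:
    if len(tissues) < 2:
        raise ValidationError("need at least 2 tissues")
    if gill_tissue not in tissues:
        raise ValidationError(f"target tissue {gill_tissue!r} not among tissues")
    n_specific = int(round(specific_fraction * n_genes))
    if specific_fraction > 0 and n_specific < 1:
        raise ValidationError("specific_fraction * n_genes must be >= 1")
    n_de = int(round(de_fraction * n_genes))
    n_module = n_modules * module_size
    if n_specific + n_de + n_module > n_genes:
        raise ValidationError("planted genes exceed n_genes")

    perm = rng.permutation(n_genes)
    cursor = 0

    specific_idx: dict[str, np.ndarray] = {}
    per_tissue = np.full(len(tissues), n_specific // len(tissues))
    per_tissue[: n_specific % len(tissues)] += 1
    for t, k in zip(tissues, per_tissue):
        specific_idx[t] = np.sort(perm[cursor : cursor + k])
        cursor += k

    n_up = n_de // 2
    de_idx_up = np.sort(perm[cursor : cursor + n_up]); cursor += n_up
    de_idx_down = np.sort(perm[cursor : cursor + (n_de - n_up)]); cursor += n_de - n_up

    module_idx: dict[str, np.ndarray] = {}
    module_factor: dict[str, np.ndarray] = {}
    labels = [f"M{i}" for i in range(n_modules)]
    for i, lab in enumerate(labels):
        module_idx[lab] = np.sort(perm[cursor : cursor + module_size])
        cursor += module_size
        if i == 0:
            f = np.array([1.0 if t == gill_tissue else 0.0 for t in tissues])
        else:
            f = rng.normal(size=len(tissues))
        module_factor[lab] = f

    # baselines: ordinary genes U(1,6); down-DE genes need headroom so the
    # depressed gill level stays positive on the log scale
    mu = rng.uniform(1.0, 6.0, size=n_genes)
    mu[de_idx_down] = rng.uniform(1.0 + effect_log2, 6.0 + effect_log2 / 2, size=len(de_idx_down))
    all_mod = np.concatenate([module_idx[m] for m in labels]) if labels else np.array([], int)
    if len(all_mod):
        mu[all_mod] = rng.uniform(3.0, 6.0, size=len(all_mod))
    specific_level = rng.uniform(1.0, 6.0, size=n_genes)

    return _GenePlan(
        n_genes=n_genes,
        tissues=tuple(tissues),
        specific_idx=specific_idx,
        specific_level=specific_level,
        de_idx_up=de_idx_up,
        de_idx_down=de_idx_down,
        de_mu=mu,
        module_idx=module_idx,
        module_factor=module_factor,
        gill_module=labels[0] if labels else "",
    )


def _render_species(
    rng: np.random.Generator,
    plan: _GenePlan,
    gene_ids: list[str],
    species: str,
    replicate_counts: dict[str, int],
    effect_log2: float,
    de_effect_log2: float,
    noise_sd: float,
    module_amplitude: float,
    gill_tissue: str,
    drop_specific: set[int] = frozenset(),
    species_gill_shift: np.ndarray | None = None,
    divergence: np.ndarray | None = None,
    counts_mode: bool = False,
) -> ExpressionDataset:
    """Draw sample-level log2 expression from the blueprint and emit a
    raw-scale dataset (raw = 2^v - 1, so log2(N+1) recovers v exactly)."""
    tissues = plan.tissues
    sample_tissue: list[str] = []
    sample_rep: list[int] = []
    for t in tissues:
        for r in range(replicate_counts[t]):
            sample_tissue.append(t)
            sample_rep.append(r + 1)
    n_samples = len(sample_tissue)
    sample_ids = [f"{species}_{t}_r{r}" for t, r in zip(sample_tissue, sample_rep)]
    tissue_arr = np.array(sample_tissue)

    # per-gene per-tissue mean on the log2 scale
    means = np.tile(plan.de_mu[:, None], (1, len(tissues)))
    off = np.zeros((plan.n_genes, len(tissues)), dtype=bool)
    gill_col = tissues.index(gill_tissue)

    for t, idx in plan.specific_idx.items():
        idx = np.array([i for i in idx if i not in drop_specific], dtype=int)
        tcol = tissues.index(t)
        off[idx, :] = True
        off[idx, tcol] = False
        means[idx, :] = 0.0
        means[idx, tcol] = effect_log2 + (plan.specific_level[idx] - 1.0) * (
            1.0 if effect_log2 > 0 else 0.0
        )
    means[plan.de_idx_up, gill_col] += de_effect_log2
    means[plan.de_idx_down, gill_col] -= de_effect_log2

    if divergence is not None:
        means = means + divergence

    tissue_col = np.array([tissues.index(t) for t in sample_tissue])
    v = means[:, tissue_col].copy()
    noise = rng.normal(scale=noise_sd, size=v.shape)
    leak = np.abs(rng.normal(scale=OFF_LEAK_SD, size=v.shape))
    off_samples = off[:, tissue_col]
    v = np.where(off_samples, leak, v + noise)

    for lab, idx in plan.module_idx.items():
        f = plan.module_factor[lab]
        # standardize the latent factor over the realized sample design
        fs = np.array([f[tissues.index(t)] for t in sample_tissue])
        fs = (fs - fs.mean()) / fs.std()
        v[idx, :] += module_amplitude * fs[None, :]

    if species_gill_shift is not None:
        gill_mask = tissue_arr == gill_tissue
        v[:, gill_mask] += species_gill_shift[:, None]

    v = np.clip(v, 0.0, None)
    raw = np.power(2.0, v) - 1.0
    if counts_mode:
        raw = rng.poisson(raw).astype(float)

    values = pd.DataFrame(raw, index=gene_ids, columns=sample_ids)
    metadata = pd.DataFrame(
        {
            "tissue": sample_tissue,
            "species": species,
            "replicate": sample_rep,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionDataset(values=values, metadata=metadata, scale="raw")


def generate_expression(
    n_genes: int = 10000,
    tissues: tuple[str, ...] = TISSUES,
    n_replicates: int = 3,
    specific_fraction: float = 0.05,
    effect_log2: float = 3.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    de_fraction: float = 0.02,
    de_effect_log2: float | None = None,
    n_modules: int = 5,
    module_size: int = 120,
    module_amplitude: float = 1.5,
    gill_tissue: str = "gills",
    species: str = "speciesA",
    counts_mode: bool = False,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """One species' raw expression matrix with planted structure.

    Returns the raw-scale dataset (enter the pipeline via
    :func:`~osmogill.expression.log_transform` and quantile normalization)
    and the ground truth of every planted gene set.
    """
    if n_genes < 1 or n_replicates < 1 or noise_sd <= 0:
        raise ValidationError("parameters must be positive")
    rng = np.random.default_rng(seed)
    plan = _make_plan(
        rng, n_genes, tuple(tissues), specific_fraction, de_fraction,
        n_modules, module_size, effect_log2, gill_tissue,
    )
    gene_ids = _gene_ids(n_genes, "g")
    ds = _render_species(
        rng, plan, gene_ids, species,
        {t: n_replicates for t in tissues},
        effect_log2,
        effect_log2 if de_effect_log2 is None else de_effect_log2,
        noise_sd, module_amplitude, gill_tissue,
        counts_mode=counts_mode,
    )
    truth = SyntheticTruth(
        specific={t: [gene_ids[i] for i in idx] for t, idx in plan.specific_idx.items()},
        de_up=[gene_ids[i] for i in plan.de_idx_up],
        de_down=[gene_ids[i] for i in plan.de_idx_down],
        modules={m: [gene_ids[i] for i in idx] for m, idx in plan.module_idx.items()},
        gill_module=plan.gill_module,
        params={
            "n_genes": n_genes, "tissues": list(tissues),
            "n_replicates": n_replicates, "specific_fraction": specific_fraction,
            "effect_log2": effect_log2, "noise_sd": noise_sd,
            "de_fraction": de_fraction, "n_modules": n_modules,
            "module_size": module_size, "module_amplitude": module_amplitude,
        },
        seed=seed,
    )
    return ds, truth


class TwoSpeciesData(NamedTuple):
    ds_a: ExpressionDataset
    ds_b: ExpressionDataset
    orthologs: OrthologTable
    truth: SyntheticTruth


def generate_two_species(
    n_genes: int = 10000,
    tissues: tuple[str, ...] = TISSUES,
    n_replicates: int = 3,
    specific_fraction: float = 0.05,
    effect_log2: float = 3.0,
    noise_sd: float = 0.5,
    divergence_noise_sd: float = 0.25,
    discordant_fraction: float = 0.0,
    species_de_fraction: float = 0.01,
    seed: int = 0,
    de_fraction: float = 0.02,
    de_effect_log2: float | None = None,
    n_modules: int = 5,
    module_size: int = 120,
    module_amplitude: float = 1.5,
    gill_tissue: str = "gills",
    species_names: tuple[str, str] = ("speciesA", "speciesB"),
    emulate_29_samples: bool = True,
) -> TwoSpeciesData:
    """Ortholog-paired two-species design sharing one planted truth.

    Species B re-renders the same blueprint with independent noise plus a
    small per-gene-per-tissue divergence shift.  A ``discordant_fraction``
    of planted gill-specific genes lose their specificity in one species
    (alternating), and a ``species_de_fraction`` of background genes get a
    between-species log2 shift inside the gill only (half elevated in A,
    half in B).  With ``emulate_29_samples`` species B's last tissue has
    one replicate fewer, yielding the 29-sample layout.
    """
    if not (0.0 <= discordant_fraction <= 1.0):
        raise ValidationError("discordant_fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)
    plan = _make_plan(
        rng, n_genes, tuple(tissues), specific_fraction, de_fraction,
        n_modules, module_size, effect_log2, gill_tissue,
    )
    ids_a = _gene_ids(n_genes, "a")
    ids_b = _gene_ids(n_genes, "b")

    # discordant gill-specific genes: specific in only one species
    gill_spec = plan.specific_idx.get(gill_tissue, np.array([], int))
    n_disc = int(round(discordant_fraction * len(gill_spec)))
    disc = rng.choice(gill_spec, size=n_disc, replace=False) if n_disc else np.array([], int)
    drop_a = set(int(i) for i in disc[::2])   # lose specificity in A
    drop_b = set(int(i) for i in disc[1::2])  # lose specificity in B

    # between-species gill DE on otherwise-background genes
    planted = set()
    for idx in plan.specific_idx.values():
        planted |= set(int(i) for i in idx)
    planted |= set(int(i) for i in plan.de_idx_up) | set(int(i) for i in plan.de_idx_down)
    for idx in plan.module_idx.values():
        planted |= set(int(i) for i in idx)
    free = np.array(sorted(set(range(n_genes)) - planted), dtype=int)
    n_sde = int(round(species_de_fraction * n_genes))
    if n_sde > len(free):
        raise ValidationError("species_de_fraction too large for remaining genes")
    sde = rng.choice(free, size=n_sde, replace=False)
    sde_a = np.sort(sde[: n_sde // 2])   # elevated in species A gills
    sde_b = np.sort(sde[n_sde // 2 :])   # elevated in species B gills
    eff_de = effect_log2 if de_effect_log2 is None else de_effect_log2
    shift_a = np.zeros(n_genes); shift_a[sde_a] = eff_de
    shift_b = np.zeros(n_genes); shift_b[sde_b] = eff_de

    div_b = rng.normal(scale=divergence_noise_sd, size=(n_genes, len(tissues)))

    reps_a = {t: n_replicates for t in tissues}
    reps_b = {t: n_replicates for t in tissues}
    if emulate_29_samples:
        last = tissues[-1]
        reps_b[last] = max(1, n_replicates - 1)

    rng_a = np.random.default_rng([seed, 1])
    rng_b = np.random.default_rng([seed, 2])
    ds_a = _render_species(
        rng_a, plan, ids_a, species_names[0], reps_a,
        effect_log2, eff_de, noise_sd, module_amplitude, gill_tissue,
        drop_specific=drop_a, species_gill_shift=shift_a,
    )
    ds_b = _render_species(
        rng_b, plan, ids_b, species_names[1], reps_b,
        effect_log2, eff_de, noise_sd, module_amplitude, gill_tissue,
        drop_specific=drop_b, species_gill_shift=shift_b, divergence=div_b,
    )

    orth = OrthologTable(list(zip(ids_a, ids_b)))
    truth = SyntheticTruth(
        specific={
            t: [ids_a[i] for i in idx if int(i) not in drop_a]
            for t, idx in plan.specific_idx.items()
        },
        specific_b={
            t: [ids_b[i] for i in idx if int(i) not in drop_b]
            for t, idx in plan.specific_idx.items()
        },
        de_up=[ids_a[i] for i in plan.de_idx_up],
        de_down=[ids_a[i] for i in plan.de_idx_down],
        modules={m: [ids_a[i] for i in idx] for m, idx in plan.module_idx.items()},
        gill_module=plan.gill_module,
        species_de_up_a=[ids_a[i] for i in sde_a],
        species_de_up_b=[ids_a[i] for i in sde_b],
        params={
            "n_genes": n_genes, "tissues": list(tissues),
            "n_replicates": n_replicates, "specific_fraction": specific_fraction,
            "effect_log2": effect_log2, "noise_sd": noise_sd,
            "divergence_noise_sd": divergence_noise_sd,
            "discordant_fraction": discordant_fraction,
            "species_de_fraction": species_de_fraction,
            "de_fraction": de_fraction, "n_modules": n_modules,
            "module_size": module_size, "module_amplitude": module_amplitude,
        },
        seed=seed,
    )
    return TwoSpeciesData(ds_a, ds_b, orth, truth)


# ---------------------------------------------------------------------------
# ontology + annotations


class OntologyAnnotations(NamedTuple):
    dag: OntologyDAG
    annotations: AnnotationMap
    clusters: dict[str, list[str]]


def generate_ontology_and_annotations(
    n_terms: int = 150,
    depth: int = 5,
    n_genes: int = 1000,
    coherence: float = 0.8,
    n_clusters: int = 5,
    terms_per_gene: tuple[int, int] = (2, 10),
    gene_groups: dict[str, list[str]] | None = None,
    namespace: str = "biological_process",
    seed: int = 0,
) -> OntologyAnnotations:
    """Random rooted GO-like DAG plus coherent gene annotations.

    The DAG has one root; ``n_clusters`` disjoint sub-DAGs hang beneath it,
    each seeded with a parent chain of length ``depth`` so the stated depth
    is realized.  Every non-root term gets 1-2 parents within its own
    cluster, is_a with probability 0.8 and part_of otherwise.  Genes draw
    2-10 distinct terms, each from the gene's home cluster with probability
    ``coherence`` and from the whole term pool otherwise.  ``gene_groups``
    (e.g. the planted tissue-specific sets) pin listed genes to dedicated
    clusters, giving each group a functionally coherent signature.
    """
    if not (n_terms >= depth >= 2):
        raise ValidationError("need n_terms >= depth >= 2")
    if n_terms < 1 + n_clusters * depth:
        raise ValidationError(
            f"n_terms={n_terms} too small for {n_clusters} clusters of depth {depth}"
        )
    if not (0.0 <= coherence <= 1.0):
        raise ValidationError("coherence must lie in [0,1]")
    rng = np.random.default_rng(seed)

    def tid(i: int) -> str:
        return f"GO:{i + 1:07d}"

    terms: dict[str, TermRecord] = {}
    parents: dict[str, list[tuple[str, str]]] = {}
    root = tid(0)
    terms[root] = TermRecord(name="root", namespace=namespace)
    parents[root] = []

    cluster_terms: dict[int, list[str]] = {c: [] for c in range(n_clusters)}
    nxt = 1
    # seed each cluster with a chain of length `depth` below the root
    for c in range(n_clusters):
        prev = root
        for level in range(depth):
            t = tid(nxt); nxt += 1
            terms[t] = TermRecord(name=f"cluster{c}_chain{level}", namespace=namespace)
            rel = "is_a" if (prev == root or rng.random() < 0.8) else "part_of"
            parents[t] = [(prev, rel)]
            cluster_terms[c].append(t)
            prev = t
    # remaining terms join clusters round-robin with 1-2 in-cluster parents
    i = 0
    while nxt < n_terms:
        c = i % n_clusters; i += 1
        t = tid(nxt); nxt += 1
        terms[t] = TermRecord(name=f"cluster{c}_term{nxt}", namespace=namespace)
        pool = cluster_terms[c]
        k = int(rng.integers(1, 3))
        picks = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        parents[t] = [
            (pool[j], "is_a" if rng.random() < 0.8 else "part_of") for j in picks
        ]
        cluster_terms[c].append(t)

    dag = OntologyDAG(terms=terms, parents=parents)

    # gene -> home cluster
    groups = dict(gene_groups or {})
    group_labels = sorted(groups)
    group_cluster = {g: i % n_clusters for i, g in enumerate(group_labels)}
    gene_home: dict[str, int] = {}
    grouped_genes = [g for lab in group_labels for g in groups[lab]]
    all_genes = list(dict.fromkeys(grouped_genes)) if gene_groups else _gene_ids(n_genes, "g")
    if gene_groups:
        extra = _gene_ids(max(0, n_genes - len(all_genes)), "bg")
        all_genes = all_genes + extra
    for lab in group_labels:
        for g in groups[lab]:
            gene_home[g] = group_cluster[lab]
    for g in all_genes:
        if g not in gene_home:
            gene_home[g] = int(rng.integers(n_clusters))

    all_terms = [t for t in terms if t != root]
    lo, hi = terms_per_gene
    ann: dict[str, frozenset[str]] = {}
    for g in all_genes:
        k = int(rng.integers(lo, hi + 1))
        home = cluster_terms[gene_home[g]]
        chosen: set[str] = set()
        guard = 0
        while len(chosen) < k and guard < 50 * k:
            guard += 1
            if rng.random() < coherence:
                chosen.add(home[int(rng.integers(len(home)))])
            else:
                chosen.add(all_terms[int(rng.integers(len(all_terms)))])
        ann[g] = frozenset(chosen)

    clusters = {
        (group_labels[c] if c < len(group_labels) else f"cluster{c}"): cluster_terms[c]
        for c in range(n_clusters)
    } if group_labels else {f"cluster{c}": cluster_terms[c] for c in range(n_clusters)}
    return OntologyAnnotations(dag, AnnotationMap(ann), clusters)


def write_obo(dag: OntologyDAG, path: str | Path) -> None:
    """Serialize a DAG to OBO 1.2 (roundtrips through parse_obo)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for t in sorted(dag.terms):
            rec = dag.terms[t]
            fh.write(f"\n[Term]\nid: {t}\nname: {rec.name}\nnamespace: {rec.namespace}\n")
            if rec.obsolete:
                fh.write("is_obsolete: true\n")
            for parent, rel in dag.parents.get(t, []):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
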