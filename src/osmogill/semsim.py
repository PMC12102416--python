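"""Wang graph-based GO semantic similarity, BMA set similarity, and the
permutation significance test for two term sets.

Wang's measure scores a term pair by the relation-weighted contributions of
their shared ancestors.  For a term t, every ancestor a receives an
S-value: S_t(t) = 1 and S_t(a) = max over children c of a (inside t's
ancestor closure) of w(relation) * S_t(c), with w(is_a) = 0.8 and
w(part_of) = 0.6 by default.  With SV(t) = sum of t's S-values,

    sim(t1, t2) = sum_{a in common ancestors} (S_t1(a) + S_t2(a))
                  / (SV(t1) + SV(t2))

Set similarity uses the best-match average (BMA): each term's best match in
the opposite set, averaged over both directions.  Significance of an
observed set similarity is assessed by drawing term sets of the same sizes
from a reference annotation universe and comparing the observed value with
the 95th percentile of the permutation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import ValidationError
from .ontology import AnnotationMap, OntologyDAG

logger = logging.getLogger(__name__)

#: GoSemSim-style graph-measure contribution weights per edge relation.
DEFAULT_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class EmptyTermSetError(ValidationError):
    """A term set is empty after namespace/obsolete filtering (distinct
    from a computed similarity of zero)."""


class WangSimilarity:
    """Cached Wang similarity over one ontology DAG.

    S-value maps and pairwise similarities are memoized, so repeated BMA
    evaluations over a fixed universe (as in the permutation test) cost a
    dictionary lookup per pair.
    """

    def __init__(self, dag: OntologyDAG, weights: dict[str, float] | None = None):
        self.dag = dag
        self.weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
        for rel, w in self.weights.items():
            if not (0.0 < w < 1.0):
                raise ValidationError(f"weight for {rel!r} must lie in (0,1), got {w}")
        self._svalues: dict[str, dict[str, float]] = {}
        self._pair: dict[tuple[str, str], float] = {}

    # -- S-values ---------------------------------------------------------
    def s_values(self, term: str) -> dict[str, float]:
        """S-value of every ancestor of ``term`` (term included)."""
        term = self.dag.resolve(term)
        cached = self._svalues.get(term)
        if cached is not None:
            return cached
        if self.dag.is_obsolete(term):
            raise ValidationError(f"term {term!r} is obsolete")
        closure = self.dag.ancestors(term)
        # children-within-closure adjacency: parent -> [(child, relation)]
        children: dict[str, list[tuple[str, str]]] = {a: [] for a in closure}
        for child in closure:
            for parent, rel in self.dag.parents.get(child, []):
                if parent in closure:
                    children[parent].append((child, rel))
        s = {term: 1.0}
        # process ancestors in increasing distance from term; S of a node
        # depends on S of its children, which are strictly closer to term
        pending = set(closure) - {term}
        while pending:
            progressed = False
            for a in list(pending):
                kids = children[a]
                if all(c in s for c, _ in kids if c in closure):
                    vals = [self.weights[rel] * s[c] for c, rel in kids if c in s]
                    if vals:
                        s[a] = max(vals)
                        pending.discard(a)
                        progressed = True
            if not progressed:  # pragma: no cover - guarded by DAG validation
                raise ValidationError("S-value propagation stalled (cyclic input?)")
        self._svalues[term] = s
        return s

    def sv(self, term: str) -> float:
        """Semantic value SV(t) = sum of t's S-values."""
        return sum(self.s_values(term).values())

    # -- pairwise ---------------------------------------------------------
    def sim(self, t1: str, t2: str) -> float:
        """Wang similarity of two non-obsolete terms of one namespace."""
        t1 = self.dag.resolve(t1)
        t2 = self.dag.resolve(t2)
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        cached = self._pair.get(key)
        if cached is not None:
            return cached
        if self.dag.namespace(t1) != self.dag.namespace(t2):
            raise ValidationError(
                f"terms {t1!r} and {t2!r} belong to different namespaces"
            )
        s1 = self.s_values(t1)
        s2 = self.s_values(t2)
        common = s1.keys() & s2.keys()
        num = sum(s1[a] + s2[a] for a in common)
        den = sum(s1.values()) + sum(s2.values())
        val = num / den
        self._pair[key] = val
        return val

    # -- set level --------------------------------------------------------
    def bma(self, terms1, terms2) -> float:
        """Best-match-average similarity of two same-namespace term sets."""
        terms1 = sorted(set(terms1))
        terms2 = sorted(set(terms2))
        if not terms1 or not terms2:
            raise EmptyTermSetError("BMA needs two non-empty term sets")
        m = np.array([[self.sim(t, u) for u in terms2] for t in terms1])
        return float((m.max(axis=1).sum() + m.max(axis=0).sum()) / (len(terms1) + len(terms2)))


def _partition_by_namespace(dag: OntologyDAG, terms) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    dropped_obsolete = 0
    for t in terms:
        t = dag.resolve(t)
        if dag.is_obsolete(t):
            dropped_obsolete += 1
            continue
        out.setdefault(dag.namespace(t), set()).add(t)
    if dropped_obsolete:
        logger.warning("dropped %d obsolete terms from a similarity set", dropped_obsolete)
    return out


def set_similarity_bma(
    sim: WangSimilarity | OntologyDAG,
    terms1,
    terms2,
) -> float:
    """BMA similarity of two term sets, combined across namespaces.

    Each shared namespace contributes its BMA weighted by how many of the
    two sets' terms it holds; terms in a namespace absent from the other
    set are dropped with a warning.
    """
    if isinstance(sim, OntologyDAG):
        sim = WangSimilarity(sim)
    p1 = _partition_by_namespace(sim.dag, terms1)
    p2 = _partition_by_namespace(sim.dag, terms2)
    if not p1 or not p2:
        raise EmptyTermSetError("a term set is empty after filtering")
    shared = sorted(p1.keys() & p2.keys())
    if not shared:
        raise EmptyTermSetError("term sets share no namespace")
    for ns in set(p1) ^ set(p2):
        logger.warning("namespace %s present in only one set; its terms are dropped", ns)
    total_w = 0.0
    acc = 0.0
    for ns in shared:
        w = len(p1[ns]) + len(p2[ns])
        acc += w * sim.bma(p1[ns], p2[ns])
        total_w += w
    return acc / total_w


@dataclass
class SetSimResult:
    """Observed BMA similarity with its permutation null distribution."""

    observed_ss: float
    perm_values: np.ndarray
    n_perm: int
    percentile_95: float
    empirical_p: float
    significant: bool
    #: fraction of permutation values strictly below the observed value —
    #: lets a LOW observed similarity be read off directly as well.
    observed_percentile: float = field(default=float("nan"))


def ss_permutation_test(
    dag: OntologyDAG | WangSimilarity,
    terms_obs1,
    terms_obs2,
    universe,
    n_perm: int = 1000,
    alpha_percentile: float = 95.0,
    seed: int | np.random.Generator | None = None,
) -> SetSimResult:
    """Permutation significance of the BMA similarity of two term sets.

    Each permutation draws |terms_obs1| and |terms_obs2| terms from
    ``universe`` without replacement (the two draws are independent and may
    overlap) and recomputes the BMA.  The observed value is significant
    when it reaches the ``alpha_percentile``-th percentile of the
    permutation values; the empirical p-value carries the +1 correction so
    it is never exactly zero.
    """
    sim = dag if isinstance(dag, WangSimilarity) else WangSimilarity(dag)
    terms_obs1 = sorted(set(terms_obs1))
    terms_obs2 = sorted(set(terms_obs2))
    if not terms_obs1 or not terms_obs2:
        raise EmptyTermSetError("observed term sets must be non-empty")
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    universe = sorted(set(universe))
    if len(universe) < max(len(terms_obs1), len(terms_obs2)):
        raise ValidationError(
            "universe smaller than an observed set "
            f"({len(universe)} < {max(len(terms_obs1), len(terms_obs2))})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = set_similarity_bma(sim, terms_obs1, terms_obs2)
    uni = np.array(universe, dtype=object)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        d1 = rng.choice(uni, size=len(terms_obs1), replace=False)
        d2 = rng.choice(uni, size=len(terms_obs2), replace=False)
        perm[i] = set_similarity_bma(sim, d1, d2)
    pct = float(np.percentile(perm, alpha_percentile))
    p = (int((perm >= observed).sum()) + 1) / (n_perm + 1)
    return SetSimResult(
        observed_ss=observed,
        perm_values=perm,
        n_perm=n_perm,
        percentile_95=pct,
        empirical_p=p,
        significant=bool(observed >= pct),
        observed_percentile=float((perm < observed).mean()),
    )


def enrich_terms(
    study_genes,
    background_genes,
    ann: AnnotationMap,
    dag: OntologyDAG,
    propagate: bool = True,
) -> pd.DataFrame:
    """One-sided hypergeometric GO term enrichment with BH adjustment.

    Annotations are propagated to ancestor terms by default (the true-path
    rule).  Only terms annotating at least one study gene are tested.
    """
    study = set(study_genes)
    background = set(background_genes)
    if not study <= background:
        extra = sorted(study - background)[0]
        raise ValidationError(f"study gene {extra!r} not in background")

    def gene_terms(g: str) -> set[str]:
        direct = ann.annotations.get(g, frozenset())
        if not propagate:
            return set(direct)
        out: set[str] = set()
        for t in direct:
            out |= dag.ancestors(dag.resolve(t))
        return out

    term_background: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for g in background:
        for t in gene_terms(g):
            term_background[t] = term_background.get(t, 0) + 1
            if g in study:
                term_study[t] = term_study.get(t, 0) + 1

    rows = []
    N, n = len(background), len(study)
    for t, k in sorted(term_study.items()):
        K = term_background[t]
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((t, k, K, p))
    df = pd.DataFrame(rows, columns=["term", "study_count", "background_count", "pvalue"])
    if len(df):
        df["padj"] = multipletests(df["pvalue"], method="fdr_bh")[1]
        df = df.sort_values("pvalue", kind="stable").reset_index(drop=True)
    else:
        df["padj"] = []
    return df
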