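"""GO ontology DAG and gene->term annotation containers.

The DAG keeps is_a and part_of edges (child -> parent), an alt_id map and
per-term obsolete flags.  Parsing of OBO 1.2 files is delegated to obonet;
validation (acyclicity, undeclared parents, namespace roots) and the
similarity machinery built on top are local.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .expression import ValidationError

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
RELATIONS = ("is_a", "part_of")


@dataclass
class TermRecord:
    name: str
    namespace: str
    obsolete: bool = False


@dataclass
class OntologyDAG:
    """GO term graph with typed child->parent edges.

    ``parents`` maps a term id to its ``(parent_id, relation)`` pairs with
    relation in {is_a, part_of}.  Obsolete terms are retained but flagged and
    take part in no edge or similarity computation.
    """

    terms: dict[str, TermRecord]
    parents: dict[str, list[tuple[str, str]]]
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, plist in self.parents.items():
            if child not in self.terms:
                raise ValidationError(f"edge from undeclared term {child!r}")
            for parent, rel in plist:
                if parent not in self.terms:
                    raise ValidationError(f"edge to undeclared term {parent!r}")
                if rel not in RELATIONS:
                    raise ValidationError(f"unsupported relation {rel!r}")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(f"ontology contains a cycle through {cycle[0][0]!r}")

    # -- structure --------------------------------------------------------
    def graph(self) -> nx.DiGraph:
        """Child->parent DiGraph over non-obsolete terms."""
        g = nx.DiGraph()
        for tid, rec in self.terms.items():
            if not rec.obsolete:
                g.add_node(tid)
        for child, plist in self.parents.items():
            if self.terms[child].obsolete:
                continue
            for parent, rel in plist:
                if not self.terms[parent].obsolete:
                    g.add_edge(child, parent, relation=rel)
        return g

    def resolve(self, term_id: str) -> str:
        """Map an alt_id to its primary id; primary ids pass through."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise ValidationError(f"unknown term id {term_id!r}")

    def is_obsolete(self, term_id: str) -> bool:
        return self.terms[self.resolve(term_id)].obsolete

    def namespace(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].namespace

    def roots(self) -> dict[str, str]:
        """The unique parentless term of each namespace."""
        out: dict[str, str] = {}
        for tid, rec in self.terms.items():
            if rec.obsolete:
                continue
            if not self.parents.get(tid):
                if rec.namespace in out:
                    raise ValidationError(
                        f"namespace {rec.namespace} has multiple roots: "
                        f"{out[rec.namespace]!r}, {tid!r}"
                    )
                out[rec.namespace] = tid
        return out

    def live_terms(self, namespace: str | None = None) -> list[str]:
        return [
            tid
            for tid, rec in self.terms.items()
            if not rec.obsolete and (namespace is None or rec.namespace == namespace)
        ]

    def ancestors(self, term_id: str) -> set[str]:
        """All ancestors of a term (via is_a/part_of), term included."""
        tid = self.resolve(term_id)
        out = {tid}
        stack = [tid]
        while stack:
            cur = stack.pop()
            for parent, _ in self.parents.get(cur, []):
                if parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out


def parse_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO 1.2 file into an :class:`OntologyDAG`.

    is_a and part_of edges are kept; other relationship types are dropped.
    Obsolete terms are retained with their flag; alt_ids resolve to their
    primary term.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)
    terms: dict[str, TermRecord] = {}
    parents: dict[str, list[tuple[str, str]]] = {}
    alt_ids: dict[str, str] = {}
    for tid, data in graph.nodes(data=True):
        if "name" not in data:
            raise ValidationError(f"edge to undeclared term {tid!r}")
        terms[tid] = TermRecord(
            name=data["name"],
            namespace=data.get("namespace", "biological_process"),
            obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = tid
    for child, parent, rel in graph.edges(keys=True):
        if rel in RELATIONS:
            parents.setdefault(child, []).append((parent, rel))
    return OntologyDAG(terms=terms, parents=parents, alt_ids=alt_ids)


@dataclass
class AnnotationMap:
    """Gene id -> set of GO term ids."""

    annotations: dict[str, frozenset[str]]

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        dag: OntologyDAG | None = None,
        on_unknown: str = "raise",
    ) -> "AnnotationMap":
        """Read a two-column (gene, term) TSV, optionally validating and
        resolving term ids against ``dag``."""
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
        return cls._build(df, dag, on_unknown)

    @classmethod
    def from_gaf(
        cls,
        path: str | Path,
        dag: OntologyDAG | None = None,
        on_unknown: str = "raise",
    ) -> "AnnotationMap":
        """Read a GAF 2.x file; columns 2 (DB object id) and 5 (GO id)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                rows.append((fields[1], fields[4]))
        df = pd.DataFrame(rows, columns=["gene", "term"])
        return cls._build(df, dag, on_unknown)

    @classmethod
    def _build(
        cls, df: pd.DataFrame, dag: OntologyDAG | None, on_unknown: str
    ) -> "AnnotationMap":
        ann: dict[str, set[str]] = {}
        dropped = 0
        for gene, term in df.itertuples(index=False):
            if dag is not None:
                try:
                    term = dag.resolve(term)
                except ValidationError:
                    if on_unknown == "drop":
                        dropped += 1
                        continue
                    raise
            ann.setdefault(gene, set()).add(term)
        if dropped:
            logger.warning("dropped %d annotations with unresolvable terms", dropped)
        return cls({g: frozenset(ts) for g, ts in ann.items()})

    def terms_of(self, genes) -> set[str]:
        """Union of terms annotated to a collection of genes."""
        out: set[str] = set()
        for g in genes:
            out |= self.annotations.get(g, frozenset())
        return out

    def term_universe(self) -> set[str]:
        """All terms annotated to at least one gene (the permutation
        universe; the whole ontology is deliberately NOT used)."""
        out: set[str] = set()
        for ts in self.annotations.values():
            out |= ts
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (g, t) for g, ts in sorted(self.annotations.items()) for t in sorted(ts)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    def __len__(self) -> int:
        return len(self.annotations)
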