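"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the production implementations:
the Wang-similarity oracle enumerates every directed path from a term to
each ancestor and maximizes the product of edge weights along the paths,
instead of the production dynamic program.
"""

import numpy as np

from osmogill.ontology import OntologyDAG, TermRecord

WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


def brute_force_s_values(dag: OntologyDAG, term: str) -> dict[str, float]:
    """S-values by explicit path enumeration (max product of weights)."""
    svals: dict[str, float] = {}

    def walk(node: str, product: float) -> None:
        if product > svals.get(node, 0.0):
            svals[node] = product
        for parent, rel in dag.parents.get(node, []):
            walk(parent, product * WEIGHTS[rel])

    walk(term, 1.0)
    return svals


def brute_force_wang(dag: OntologyDAG, t1: str, t2: str) -> float:
    s1 = brute_force_s_values(dag, t1)
    s2 = brute_force_s_values(dag, t2)
    common = s1.keys() & s2.keys()
    return sum(s1[a] + s2[a] for a in common) / (sum(s1.values()) + sum(s2.values()))


def random_toy_dag(rng: np.random.Generator, n_terms: int = 20) -> OntologyDAG:
    """Random single-namespace DAG: term i draws 1-2 parents among 0..i-1."""
    terms = {f"T{i}": TermRecord(name=f"T{i}", namespace="biological_process")
             for i in range(n_terms)}
    parents: dict[str, list[tuple[str, str]]] = {"T0": []}
    for i in range(1, n_terms):
        k = int(rng.integers(1, 3))
        picks = rng.choice(i, size=min(k, i), replace=False)
        parents[f"T{i}"] = [
            (f"T{j}", "is_a" if rng.random() < 0.8 else "part_of") for j in picks
        ]
    return OntologyDAG(terms=terms, parents=parents)
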