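import numpy as np
import pandas as pd
import pytest

from osmogill.expression import ExpressionDataset
from osmogill.ontology import OntologyDAG, TermRecord


@pytest.fixture
def toy_dag() -> OntologyDAG:
    """Four-term DAG: R root; A is_a R; B is_a R; C is_a A."""
    return OntologyDAG(
        terms={t: TermRecord(name=t, namespace="biological_process") for t in "RABC"},
        parents={"R": [], "A": [("R", "is_a")], "B": [("R", "is_a")], "C": [("A", "is_a")]},
    )


def make_dataset(values: np.ndarray, tissues, genes=None, scale="raw", species="sp"):
    """Small dataset helper: one sample per entry of `tissues`."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    reps: dict[str, int] = {}
    sample_ids, rep_idx = [], []
    for t in tissues:
        reps[t] = reps.get(t, 0) + 1
        sample_ids.append(f"{t}_r{reps[t]}")
        rep_idx.append(reps[t])
    vals = pd.DataFrame(values, index=genes, columns=sample_ids)
    meta = pd.DataFrame(
        {"tissue": list(tissues), "species": species, "replicate": rep_idx},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionDataset(values=vals, metadata=meta, scale=scale)


@pytest.fixture
def make_ds():
    return make_dataset
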