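#!/usr/bin/env python
"""Call specifically expressed genes per tissue via the tau index.

Normalizes each species' matrix (log2(N+1), quantile normalization),
computes per-gene tau over tissue means, calls genes with tau > 0.9 whose
top-expressing samples all come from the top tissue, and intersects the
two species' gill sets over the ortholog table ("common" gill genes).
"""

import argparse
from pathlib import Path

import pandas as pd

from osmogill.expression import (
    OrthologTable,
    load_dataset,
    log_transform,
    quantile_normalize,
    tissue_means,
)
from osmogill.specificity import call_specific_genes, common_specific_genes, tau_table

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

sets = {}
for sp in ("a", "b"):
    ds = load_dataset(args.data / f"matrix_{sp}.tsv", args.data / f"metadata_{sp}.tsv")
    norm = quantile_normalize(log_transform(ds))
    tt = tau_table(tissue_means(norm), norm)
    sets[sp] = call_specific_genes(tt, norm, threshold=0.9)
    tt["specific_in"] = ""
    for tissue, genes in sets[sp].items():
        tt.loc[sorted(genes), "specific_in"] = tissue
    tt.to_csv(args.out / f"tau_{sp}.tsv", sep="\t", index_label="gene")
    counts = ", ".join(f"{t}: {len(s)}" for t, s in sorted(sets[sp].items()))
    print(f"species {sp} specific genes -- {counts}")

orth = OrthologTable.from_tsv(args.data / "orthologs.tsv")
common = common_specific_genes(sets["a"], sets["b"], orth, "gills")
pd.DataFrame(sorted(common), columns=["gene_a", "gene_b"]).to_csv(
    args.out / "common_gill_specific.tsv", sep="\t", index=False
)
print(f"{len(common)} ortholog pairs are gill-specific in BOTH species")
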