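#!/usr/bin/env python
"""Gill differential expression: within-species 4-way intersection and
the between-species gill comparison.

Per species, genes differentially expressed between the gill and each of
the four other tissues (P < 0.05, |log2FC| >= 1) are intersected with
direction consistency — only genes up (or down) against ALL four tissues
count as gill DEGs.  Gill samples of the two species are then compared
over the ortholog pairing, and the overlap between tissue-level and
species-level gill DEGs is reported.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from osmogill.differential import filter_degs, intersect_deg_sets, two_group_de
from osmogill.expression import (
    ExpressionDataset,
    OrthologTable,
    load_dataset,
    log_transform,
    pair_orthologs,
    quantile_normalize,
)

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

ds_a = load_dataset(args.data / "matrix_a.tsv", args.data / "metadata_a.tsv")
ds_b = load_dataset(args.data / "matrix_b.tsv", args.data / "metadata_b.tsv")
orth = OrthologTable.from_tsv(args.data / "orthologs.tsv")
ds_a, ds_b = pair_orthologs(ds_a, ds_b, orth)
norm = {"a": quantile_normalize(log_transform(ds_a)),
        "b": quantile_normalize(log_transform(ds_b))}

report: dict = {}
tissue_degs = {}
for sp, ds in norm.items():
    gill = ds.samples_of_tissue("gills")
    sets = []
    for tissue in ds.tissues:
        if tissue == "gills":
            continue
        table = two_group_de(ds, gill, ds.samples_of_tissue(tissue),
                             comparison=f"{sp}:gills_vs_{tissue}")
        table.to_tsv(args.out / f"de_{sp}_gills_vs_{tissue}.tsv")
        sets.append(filter_degs(table))
    inter, counts = intersect_deg_sets(sets)
    tissue_degs[sp] = inter
    report[sp] = counts
    print(
        f"species {sp}: gill DEGs vs all four tissues -- "
        f"{len(inter.up)} up, {len(inter.down)} down"
    )

# between-species comparison within the gill, over ortholog pairs
vals_b = norm["b"].values.set_axis(norm["a"].values.index, axis=0)
gill_a = norm["a"].samples_of_tissue("gills")
gill_b = norm["b"].samples_of_tissue("gills")
gill_ds = ExpressionDataset(
    values=pd.concat([norm["a"].values[gill_a], vals_b[gill_b]], axis=1),
    metadata=pd.concat([norm["a"].metadata.loc[gill_a], norm["b"].metadata.loc[gill_b]]),
    scale="log",
)
table = two_group_de(gill_ds, gill_a, gill_b, comparison="gills:a_vs_b")
table.to_tsv(args.out / "de_species_gill.tsv")
species = filter_degs(table)
report["species_gill"] = {"up": len(species.up), "down": len(species.down)}
print(f"between species (gill): {len(species.up)} up in A, {len(species.down)} up in B")

report["shared"] = {
    "a_tissue_up_and_species_up": len(tissue_degs["a"].up & species.up),
    "a_tissue_down_and_species_down": len(tissue_degs["a"].down & species.down),
}
with open(args.out / "deg_venn.json", "w") as fh:
    json.dump(report, fh, indent=1, sort_keys=True)
print(
    f"{report['shared']['a_tissue_up_and_species_up']} genes are gill-up in A "
    "against both the other tissues and the other species"
)
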