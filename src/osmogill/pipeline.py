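"""End-to-end orchestration: normalize -> tau -> semantic similarity ->
DEG intersection -> co-expression hubs, over synthetic or user inputs.

All thresholds default to the analysis design's standard values (tau 0.9; P 0.05;
|log2FC| 1; 1000 permutations at the 95th percentile; MM 0.8; |GS| 0.2;
edge weight 0.3; merge height 0.2; minimum module size 100).  Every output
table carries a header comment with the tool version, the configuration
hash and the seed, and the machine-readable summary is byte-stable for a
fixed seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .coexpression import (
    ModuleAssignment,
    membership_and_significance,
    merge_close_modules,
    module_eigengene,
    module_trait_correlation,
    select_hub_genes,
    tissue_trait_matrix,
    tom_edge_list,
)
from .differential import filter_degs, intersect_deg_sets, two_group_de
from .expression import (
    ExpressionDataset,
    OrthologTable,
    ValidationError,
    load_dataset,
    log_transform,
    pair_orthologs,
    quantile_normalize,
    tissue_means,
)
from .ontology import AnnotationMap, parse_obo
from .semsim import WangSimilarity, ss_permutation_test
from .simulate import (
    SyntheticTruth,
    generate_ontology_and_annotations,
    generate_two_species,
    write_obo,
)
from .specificity import call_specific_genes, common_specific_genes, tau_table

logger = logging.getLogger(__name__)

#: the default calling thresholds of the analysis design
DEFAULT_THRESHOLDS = {
    "tau": 0.9,
    "p_value": 0.05,
    "log2fc": 1.0,
    "n_perm": 1000,
    "percentile": 95.0,
    "mm": 0.8,
    "gs": 0.2,
    "edge_weight": 0.3,
    "merge_height": 0.2,
    "min_module_size": 100,
    "tom_beta": 6.0,
}

DEFAULT_SYNTHETIC = {
    "n_genes": 2000,
    "n_replicates": 3,
    "specific_fraction": 0.05,
    "effect_log2": 3.0,
    "noise_sd": 0.5,
    "de_fraction": 0.02,
    "n_modules": 5,
    "module_size": 120,
    "module_amplitude": 1.5,
    "divergence_noise_sd": 0.25,
    "discordant_fraction": 0.1,
    "species_de_fraction": 0.01,
    "ontology": {"n_terms": 150, "depth": 5, "coherence": 0.9, "n_clusters": 5},
}

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "results/pipeline",
    "gill_tissue": "gills",
    "stages": {"tau": True, "semsim": True, "deg": True, "coexpression": True},
    "thresholds": dict(DEFAULT_THRESHOLDS),
    "synthetic": dict(DEFAULT_SYNTHETIC),
    "inputs": None,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def make_config(overrides: dict | None = None) -> dict:
    """Deep-merge user overrides onto the defaults and validate."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if overrides:
        merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    t = cfg["thresholds"]
    if not (0.0 < t["tau"] < 1.0):
        raise ValidationError(f"tau threshold must lie in (0,1), got {t['tau']}")
    if not (0.0 < t["p_value"] <= 1.0):
        raise ValidationError("p_value threshold must lie in (0,1]")
    if t["log2fc"] <= 0:
        raise ValidationError("log2fc threshold must be positive")
    if t["n_perm"] < 1:
        raise ValidationError("n_perm must be >= 1")
    if not (0.0 < t["percentile"] < 100.0):
        raise ValidationError("percentile must lie in (0,100)")
    for key in ("mm", "gs", "edge_weight"):
        if not (0.0 <= t[key] <= 1.0):
            raise ValidationError(f"{key} threshold must lie in [0,1]")
    if not (0.0 < t["merge_height"] < 1.0):
        raise ValidationError("merge_height must lie in (0,1)")
    if cfg["inputs"] is None and cfg["synthetic"] is None:
        raise ValidationError("config needs either inputs or a synthetic block")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _header(cfg: dict) -> str:
    return f"# osmogill {__version__} config={config_hash(cfg)} seed={cfg['seed']}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: dict, index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index_label=index_label)


def _normalize(ds: ExpressionDataset) -> ExpressionDataset:
    return quantile_normalize(log_transform(ds))


def run_pipeline(config: dict | None = None, output_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and return the summary report.

    On a stage failure the partial outputs are retained next to a FAILED
    marker naming the stage, and :class:`StageError` is raised.
    """
    cfg = make_config(config or {})
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    th = cfg["thresholds"]
    gill = cfg["gill_tissue"]
    summary: dict = {
        "tool": "osmogill",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "stages": {},
    }

    stage = "inputs"
    try:
        if cfg["inputs"] is None:
            syn = cfg["synthetic"]
            sim = generate_two_species(
                n_genes=syn["n_genes"],
                n_replicates=syn["n_replicates"],
                specific_fraction=syn["specific_fraction"],
                effect_log2=syn["effect_log2"],
                noise_sd=syn["noise_sd"],
                divergence_noise_sd=syn["divergence_noise_sd"],
                discordant_fraction=syn["discordant_fraction"],
                species_de_fraction=syn["species_de_fraction"],
                de_fraction=syn["de_fraction"],
                n_modules=syn["n_modules"],
                module_size=syn["module_size"],
                module_amplitude=syn["module_amplitude"],
                gill_tissue=gill,
                seed=seed,
            )
            ds_a, ds_b, orth, truth = sim
            data_dir = out / "data"
            data_dir.mkdir(exist_ok=True)
            ds_a.to_tsv(data_dir / "matrix_a.tsv", data_dir / "metadata_a.tsv")
            ds_b.to_tsv(data_dir / "matrix_b.tsv", data_dir / "metadata_b.tsv")
            orth.to_tsv(data_dir / "orthologs.tsv")
            truth.to_json(data_dir / "truth.json")
            assign_src = {g: m for m, genes in truth.modules.items() for g in genes}
        else:
            inp = cfg["inputs"]
            ds_a = load_dataset(inp["matrix_a"], inp["metadata_a"])
            ds_b = load_dataset(inp["matrix_b"], inp["metadata_b"])
            orth = OrthologTable.from_tsv(inp["orthologs"])
            truth = None
            assign_src = None
            if inp.get("modules"):
                assign_src = dict(
                    ModuleAssignment.from_tsv(
                        inp["modules"], min_size=th["min_module_size"]
                    ).labels
                )
        ds_a, ds_b = pair_orthologs(ds_a, ds_b, orth)
        norm_a = _normalize(ds_a)
        norm_b = _normalize(ds_b)
        summary["stages"]["inputs"] = {
            "n_pairs": ds_a.n_genes,
            "n_samples": ds_a.n_samples + ds_b.n_samples,
        }

        specific_a = specific_b = None
        if cfg["stages"].get("tau", True):
            stage = "tau"
            taus = {}
            for name, ds in (("a", norm_a), ("b", norm_b)):
                profile = tissue_means(ds)
                tt = tau_table(profile, ds)
                _write_tsv(tt, out / f"tau_{name}.tsv", cfg, index_label="gene")
                taus[name] = (tt, ds)
            specific_a = call_specific_genes(*taus["a"], threshold=th["tau"])
            specific_b = call_specific_genes(*taus["b"], threshold=th["tau"])
            common = common_specific_genes(specific_a, specific_b, orth, gill)
            pd.DataFrame(sorted(common), columns=["gene_a", "gene_b"]).to_csv(
                out / "common_gill_specific.tsv", sep="\t", index=False
            )
            summary["stages"]["tau"] = {
                "specific_per_tissue_a": {t: len(s) for t, s in sorted(specific_a.items())},
                "specific_per_tissue_b": {t: len(s) for t, s in sorted(specific_b.items())},
                "common_gill_specific": len(common),
            }

        if cfg["stages"].get("semsim", True) and specific_a is not None:
            stage = "semsim"
            if cfg["inputs"] is None:
                onto = generate_ontology_and_annotations(
                    n_terms=syn["ontology"]["n_terms"],
                    depth=syn["ontology"]["depth"],
                    n_genes=ds_a.n_genes,
                    coherence=syn["ontology"]["coherence"],
                    n_clusters=syn["ontology"]["n_clusters"],
                    gene_groups={t: sorted(s) for t, s in specific_a.items() if s},
                    seed=seed,
                )
                dag, ann = onto.dag, onto.annotations
                write_obo(dag, out / "data" / "ontology.obo")
                ann.to_tsv(out / "data" / "annotations.tsv")
            else:
                dag = parse_obo(cfg["inputs"]["obo"])
                ann = AnnotationMap.from_tsv(cfg["inputs"]["annotations"], dag)
            sim = WangSimilarity(dag)
            universe = ann.term_universe()
            gill_terms = ann.terms_of(specific_a.get(gill, set()))
            rows = []
            for other in sorted(specific_a):
                if other == gill or not specific_a[other]:
                    continue
                other_terms = ann.terms_of(specific_a[other])
                if not gill_terms or not other_terms:
                    continue
                res = ss_permutation_test(
                    sim, gill_terms, other_terms, universe,
                    n_perm=int(th["n_perm"]),
                    alpha_percentile=th["percentile"],
                    seed=seed,
                )
                rows.append(
                    {
                        "pair": f"{gill}_vs_{other}",
                        "observed_ss": round(res.observed_ss, 10),
                        "percentile_95": round(res.percentile_95, 10),
                        "empirical_p": round(res.empirical_p, 10),
                        "observed_percentile": round(res.observed_percentile, 10),
                        "significant": res.significant,
                    }
                )
            df = pd.DataFrame(rows)
            _write_tsv(df.set_index("pair"), out / "semsim.tsv", cfg, index_label="pair")
            summary["stages"]["semsim"] = {
                r["pair"]: {
                    "observed_ss": r["observed_ss"],
                    "percentile_95": r["percentile_95"],
                    "empirical_p": r["empirical_p"],
                    "significant": bool(r["significant"]),
                }
                for r in rows
            }

        if cfg["stages"].get("deg", True):
            stage = "deg"
            deg_summary = {}
            intersections = {}
            for name, ds in (("a", norm_a), ("b", norm_b)):
                gill_samples = ds.samples_of_tissue(gill)
                sets = []
                for other in ds.tissues:
                    if other == gill:
                        continue
                    table = two_group_de(
                        ds, gill_samples, ds.samples_of_tissue(other),
                        comparison=f"{name}:{gill}_vs_{other}",
                    )
                    _write_tsv(
                        table.stats, out / f"de_{name}_{gill}_vs_{other}.tsv",
                        cfg, index_label="gene",
                    )
                    sets.append(filter_degs(table, th["p_value"], th["log2fc"]))
                inter, counts = intersect_deg_sets(sets)
                intersections[name] = inter
                deg_summary[name] = counts
            # between-species gill comparison over the paired matrices
            combined = pd.concat(
                [
                    norm_a.values[norm_a.samples_of_tissue(gill)],
                    norm_b.values[norm_b.samples_of_tissue(gill)].set_axis(
                        norm_a.values.index, axis=0
                    ),
                ],
                axis=1,
            )
            meta = pd.concat(
                [
                    norm_a.metadata.loc[norm_a.samples_of_tissue(gill)],
                    norm_b.metadata.loc[norm_b.samples_of_tissue(gill)],
                ]
            )
            gill_ds = ExpressionDataset(values=combined, metadata=meta, scale="log")
            sp = meta["species"].unique()
            table = two_group_de(
                gill_ds,
                list(meta.index[meta["species"] == sp[0]]),
                list(meta.index[meta["species"] == sp[1]]),
                comparison=f"{gill}:{sp[0]}_vs_{sp[1]}",
            )
            _write_tsv(table.stats, out / "de_species_gill.tsv", cfg, index_label="gene")
            species_degs = filter_degs(table, th["p_value"], th["log2fc"])
            deg_summary["species_gill"] = {
                "up": len(species_degs.up),
                "down": len(species_degs.down),
            }
            # tissue-DEGs that are also species-DEGs (shared-direction)
            deg_summary["shared"] = {
                "a_up_and_species_up": len(intersections["a"].up & species_degs.up),
                "a_down_and_species_down": len(intersections["a"].down & species_degs.down),
            }
            with open(out / "deg_venn.json", "w") as fh:
                json.dump(deg_summary, fh, indent=1, sort_keys=True)
            summary["stages"]["deg"] = deg_summary

        if cfg["stages"].get("coexpression", True) and assign_src:
            stage = "coexpression"
            # combined 2-species matrix over ortholog pairs (A gene ids)
            vals_b = norm_b.values.set_axis(norm_a.values.index, axis=0)
            combined = pd.concat([norm_a.values, vals_b], axis=1)
            meta = pd.concat([norm_a.metadata, norm_b.metadata])
            ds_all = ExpressionDataset(values=combined, metadata=meta, scale="log")
            assign = ModuleAssignment(
                {g: m for g, m in assign_src.items() if g in combined.index},
                min_size=min(
                    th["min_module_size"],
                    min(pd.Series(assign_src).value_counts()),
                ),
            )
            assign = merge_close_modules(ds_all, assign, th["merge_height"])
            eig = module_eigengene(ds_all, assign)
            traits = tissue_trait_matrix(ds_all)
            r, p = module_trait_correlation(eig, traits)
            _write_tsv(r, out / "module_trait_r.tsv", cfg, index_label="module")
            _write_tsv(p, out / "module_trait_p.tsv", cfg, index_label="module")
            report = membership_and_significance(ds_all, assign, eig, traits, gill)
            report = select_hub_genes(report, th["mm"], th["gs"])
            _write_tsv(report, out / "hub_report.tsv", cfg, index_label="gene")
            top_module = r[gill].idxmax()
            hub_genes = report.index[(report["module"] == top_module) & report["hub"]]
            edges = tom_edge_list(
                ds_all, assign.genes_of(top_module),
                beta=th["tom_beta"], weight_cutoff=th["edge_weight"],
            )
            edges["weight"] = edges["weight"].round(10)
            _write_tsv(edges.set_index("source"), out / "edges.tsv", cfg, index_label="source")
            summary["stages"]["coexpression"] = {
                "n_modules": len(assign.modules()),
                "module_sizes": assign.sizes(),
                "top_gill_module": str(top_module),
                "top_gill_r": round(float(r.loc[top_module, gill]), 10),
                "n_hub_genes_top_module": int(len(hub_genes)),
                "n_edges": int(len(edges)),
            }
    except Exception as exc:  # noqa: BLE001 - re-raised as StageError
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
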