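"""Differential-expression thresholding, set intersection, and 2^-ddCt.

The DE test itself is deliberately plain plumbing (Welch t on log-scale
means); the substance here is the calling rule — P < 0.05 and
|log2FC| >= 1 (fold change >= 2) — the direction-consistent intersection of
gill-versus-each-other-tissue DEG sets, and relative qPCR quantification by
the 2^-ddCt method against a reference gene and a control condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionDataset, ValidationError


@dataclass
class DETable:
    """Per-gene differential statistics for one comparison."""

    comparison: str
    stats: pd.DataFrame  # index gene; columns log2fc, pvalue, [padj]

    def __post_init__(self) -> None:
        for col in ("log2fc", "pvalue"):
            if col not in self.stats.columns:
                raise ValidationError(f"DE table lacks column {col!r}")
        if self.stats.index.duplicated().any():
            g = self.stats.index[self.stats.index.duplicated()][0]
            raise ValidationError(f"duplicate gene {g!r} in DE table")
        p = self.stats["pvalue"].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
            raise ValidationError("p-values must lie in [0,1]")
        if not np.isfinite(self.stats["log2fc"].to_numpy(dtype=float)).all():
            raise ValidationError("log2FC must be finite")

    @classmethod
    def from_tsv(cls, path: str | Path, comparison: str | None = None) -> "DETable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(comparison or Path(path).stem, df)

    def to_tsv(self, path: str | Path) -> None:
        self.stats.to_csv(path, sep="\t", index_label="gene")


@dataclass
class DEGSets:
    """Up- and down-regulated gene sets for one comparison."""

    comparison: str
    up: set[str]
    down: set[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValidationError("a gene cannot be both up- and down-regulated")


def two_group_de(
    ds: ExpressionDataset,
    groupA,
    groupB,
    comparison: str = "A_vs_B",
) -> DETable:
    """Welch two-sample t-test per gene on log-scale data.

    log2FC = mean(A) - mean(B).  Genes with zero variance in both groups
    get p = 1 when the means are equal and p = 0 otherwise (degenerate
    convention).  BH-adjusted p-values are reported alongside.
    """
    groupA, groupB = list(groupA), list(groupB)
    if set(groupA) & set(groupB):
        raise ValidationError("groups overlap")
    if len(groupA) < 2 or len(groupB) < 2:
        raise ValidationError("each group needs at least 2 samples")
    if ds.scale != "log":
        raise ValidationError("two_group_de expects log-scale data")
    a = ds.values[groupA].to_numpy(dtype=float)
    b = ds.values[groupB].to_numpy(dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical groups (e.g. jointly silent genes) trip scipy's
        # catastrophic-cancellation warning; the degenerate cases are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate, np.where(lfc == 0, 1.0, 0.0), p)
    p = np.nan_to_num(p, nan=1.0)
    out = pd.DataFrame({"log2fc": lfc, "pvalue": p}, index=ds.values.index)
    out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return DETable(comparison, out)


def filter_degs(t: DETable, p_max: float = 0.05, lfc_min: float = 1.0) -> DEGSets:
    """Call DEGs at P < p_max and |log2FC| >= lfc_min.

    The fold-change boundary is included (>=), the p boundary excluded (<),
    matching the "fold change >= 2 (log2|FC| >= 1), P < 0.05" convention.
    The raw p-value is used for calling; the BH-adjusted p is reported in
    the table but deliberately not applied.
    """
    if p_max <= 0 or lfc_min <= 0:
        raise ValidationError("thresholds must be positive")
    df = t.stats
    sig = df["pvalue"] < p_max
    up = set(df.index[sig & (df["log2fc"] >= lfc_min)])
    down = set(df.index[sig & (df["log2fc"] <= -lfc_min)])
    return DEGSets(t.comparison, up, down)


def intersect_deg_sets(
    sets: list[DEGSets],
    mode: str = "direction_consistent",
) -> tuple[DEGSets, dict]:
    """Intersect DEG sets across comparisons.

    ``direction_consistent`` (default): a gene must be up in every
    comparison (or down in every comparison).  ``membership``: a gene must
    merely appear in every comparison's DEG list; its direction in the
    first comparison is reported.  Also returns per-comparison, pairwise
    and overall overlap counts for Venn-style reporting.
    """
    if not sets:
        raise ValidationError("need at least one DEG set")
    if mode not in ("direction_consistent", "membership"):
        raise ValidationError(f"unknown intersection mode {mode!r}")
    if mode == "direction_consistent":
        up = set.intersection(*[s.up for s in sets])
        down = set.intersection(*[s.down for s in sets])
    else:
        members = set.intersection(*[s.up | s.down for s in sets])
        up = members & sets[0].up
        down = members & sets[0].down
    label = "intersection(" + ",".join(s.comparison for s in sets) + ")"
    counts = {
        "mode": mode,
        "per_comparison": {
            s.comparison: {"up": len(s.up), "down": len(s.down)} for s in sets
        },
        "pairwise": {
            f"{s1.comparison}&{s2.comparison}": {
                "up": len(s1.up & s2.up),
                "down": len(s1.down & s2.down),
            }
            for i, s1 in enumerate(sets)
            for s2 in sets[i + 1 :]
        },
        "intersection": {"up": len(up), "down": len(down)},
    }
    return DEGSets(label, up, down), counts


def delta_delta_ct(
    q: pd.DataFrame,
    control_condition: str,
) -> pd.DataFrame:
    """Relative expression per condition by the 2^-ddCt method.

    ``q`` holds one row per reaction with columns sample, condition,
    ct_target, ct_reference.  dCt = Ct_target - Ct_reference per sample;
    ddCt = mean dCt(condition) - mean dCt(control); relative expression =
    2^-ddCt, so the control condition maps to exactly 1.
    """
    for col in ("sample", "condition", "ct_target", "ct_reference"):
        if col not in q.columns:
            raise ValidationError(f"qPCR table lacks column {col!r}")
    if (q["ct_target"] <= 0).any() or (q["ct_reference"] <= 0).any():
        raise ValidationError("Ct values must be positive")
    if control_condition not in set(q["condition"]):
        raise ValidationError(f"control condition {control_condition!r} missing")
    dct = (q["ct_target"] - q["ct_reference"]).groupby(q["condition"]).mean()
    ddct = dct - dct[control_condition]
    out = pd.DataFrame(
        {
            "delta_ct": dct,
            "delta_delta_ct": ddct,
            "relative_expression": np.power(2.0, -ddct),
        }
    )
    out.index.name = "condition"
    return out
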