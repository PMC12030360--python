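"""Differential-expression overlays: DEG filtering, group densities, strand folds.

The DEG filter is the standard DESeq2 downstream rule: a gene is
upregulated when log2FoldChange >= +cut and padj <= padj_cut, downregulated
when log2FoldChange <= -cut and padj <= padj_cut, otherwise not significant
(ns). Group-wise densities restrict both numerator and denominator to the
listed genes' regions, and per-gene strand folds reuse the max/min G4SDF
convention so the selection rule "fold > cutoff" is orientation-free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import CONTEXTS, FeatureRegion, total_span
from .stats import DensityRecord, density

logger = logging.getLogger("g4scape")

#: accepted aliases for the DESeq2-style result columns
_COLUMN_ALIASES = {
    "gene_id": ("gene_id", "gene", "id", "row"),
    "log2FoldChange": ("log2FoldChange", "log2fc", "lfc"),
    "padj": ("padj", "p_adj", "fdr", "qvalue"),
}


def _resolve_columns(table: pd.DataFrame) -> pd.DataFrame:
    renames = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in table.columns:
                renames[alias] = canonical
                break
        else:
            raise ValueError(f"missing required column {canonical!r} (aliases: {aliases})")
    return table.rename(columns=renames)


def filter_degs(
    table: pd.DataFrame,
    lfc_cut: float = 1.0,
    padj_cut: float = 0.05,
    timepoint: str = "",
) -> pd.DataFrame:
    """Classify every gene of a results table as up / down / ns.

    Missing padj is treated as not significant. Duplicate gene IDs are an
    error (they would double-count regions downstream).
    """
    table = _resolve_columns(table.copy())
    dup = table["gene_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate gene_id(s): {sorted(table.loc[dup, 'gene_id'])[:5]}")
    lfc = pd.to_numeric(table["log2FoldChange"], errors="coerce")
    padj = pd.to_numeric(table["padj"], errors="coerce")
    significant = padj.notna() & (padj <= padj_cut)
    direction = np.where(
        significant & (lfc >= lfc_cut),
        "up",
        np.where(significant & (lfc <= -lfc_cut), "down", "ns"),
    )
    out = table[["gene_id", "log2FoldChange", "padj"]].copy()
    out["direction"] = direction
    out["timepoint"] = timepoint
    return out


def read_deg_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def group_densities(
    gene_ids: Sequence[str],
    assignment: pd.DataFrame,
    regions: Sequence[FeatureRegion],
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Region densities restricted to a gene list (e.g. the up-DEGs).

    Denominators are the interval unions of the listed genes' regions only;
    numerators count distinct hits assigned to those genes' regions. With
    the full gene universe this reproduces :func:`g4scape.stats.region_densities`.
    """
    gene_set = set(gene_ids)
    if not gene_set:
        logger.warning("empty gene list for group_densities")
    regs = [r for r in regions if r.gene_id in gene_set]
    sub = assignment[assignment["gene_id"].isin(gene_set)]
    if classes is None:
        classes = sorted({r.region_class for r in regions})
    by_class: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for r in regs:
        by_class.setdefault(r.region_class, {}).setdefault(r.seq_id, []).append(
            (r.start, r.end)
        )
    rows = []
    for cls in classes:
        span = sum(total_span(ivs) for ivs in by_class.get(cls, {}).values())
        cls_sub = sub[sub["region_class"] == cls]
        counts = {
            "double": cls_sub["hit_idx"].nunique(),
            "coding": cls_sub.loc[cls_sub["context"] == "coding", "hit_idx"].nunique(),
            "template": cls_sub.loc[cls_sub["context"] == "template", "hit_idx"].nunique(),
        }
        for ctx in CONTEXTS:
            rows.append(
                DensityRecord(cls, ctx, counts[ctx], span, density(counts[ctx], span), span <= 0)
            )
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class DEGSelection:
    """Genes whose per-gene strand fold in one region class exceeds the cutoff."""

    timepoint: str
    direction: str
    region_class: str
    fold_cutoff: float
    selected: list[str] = field(default_factory=list)
    infinite_fold: list[str] = field(default_factory=list)  # one strand zero; flagged


def per_gene_strand_densities(
    gene_class_counts: pd.DataFrame,
    regions: Sequence[FeatureRegion],
    region_class: str,
) -> pd.DataFrame:
    """Per-gene coding/template densities in one class (equal strand spans)."""
    spans: dict[str, int] = {}
    for r in regions:
        if r.region_class == region_class:
            spans[r.gene_id] = spans.get(r.gene_id, 0) + r.span
    sub = gene_class_counts[gene_class_counts["region_class"] == region_class]
    rows = []
    for row in sub.itertuples(index=False):
        span = spans.get(row.gene_id, 0)
        rows.append(
            (
                row.gene_id,
                span,
                density(row.coding, span) if span else float("nan"),
                density(row.template, span) if span else float("nan"),
            )
        )
    return pd.DataFrame(rows, columns=["gene_id", "span_bp", "coding_density", "template_density"])


def select_by_fold(
    per_gene: pd.DataFrame,
    region_class: str,
    fold_cutoff: float = 3.0,
    timepoint: str = "",
    direction: str = "",
    pooled: bool = False,
) -> DEGSelection:
    """Select genes with strand fold (max/min) strictly above the cutoff.

    Genes with one strand zero and the other nonzero count as infinite fold:
    selected and flagged. Genes with zero on both strands are excluded.
    With ``pooled=True`` the fold is computed once on summed counts and the
    selection is all-or-nothing for the listed genes.
    """
    sel = DEGSelection(timepoint, direction, region_class, fold_cutoff)
    usable = per_gene.dropna(subset=["coding_density", "template_density"])
    if pooled:
        cd = usable["coding_density"].sum()
        td = usable["template_density"].sum()
        if cd == 0 and td == 0:
            return sel
        fold = float("inf") if min(cd, td) == 0 else max(cd, td) / min(cd, td)
        if fold > fold_cutoff:
            sel.selected = sorted(usable["gene_id"])
        return sel
    for row in usable.itertuples(index=False):
        cd, td = row.coding_density, row.template_density
        if cd == 0 and td == 0:
            continue
        if min(cd, td) == 0:
            sel.selected.append(row.gene_id)
            sel.infinite_fold.append(row.gene_id)
            continue
        if max(cd, td) / min(cd, td) > fold_cutoff:
            sel.selected.append(row.gene_id)
    sel.selected.sort()
    sel.infinite_fold.sort()
    return sel
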