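"""Densities, strand bias, gene classification and chromosome correlations.

Density is hits per kilobase: ``count * 1000 / span_bp``. Strand bias is
summarised as the fold difference between coding- and template-strand
densities (max/min convention, >= 1, orientation recorded) and tested with
an exact two-sided binomial on the counts: within one region class the two
strand contexts share the same interval span, so under no bias a hit falls
on either strand with probability 1/2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import CONTEXTS, REGION_CLASSES, FeatureRegion, class_union_spans

logger = logging.getLogger("g4scape")


@dataclass(frozen=True)
class DensityRecord:
    region_class: str
    context: str
    hit_count: int
    span_bp: int
    density: float
    flagged: bool = False


@dataclass(frozen=True)
class StrandBiasRecord:
    region_class: str
    coding_density: float
    template_density: float
    g4sdf: float
    dominant: str
    flagged: bool = False


def density(hit_count: int, span_bp: int) -> float:
    """Hits per kbp; NaN (callers flag the record) when the span is empty."""
    if span_bp <= 0:
        return float("nan")
    return hit_count * 1000.0 / span_bp


def region_densities(
    assignment: pd.DataFrame,
    regions: Sequence[FeatureRegion],
    classes: Sequence[str] = REGION_CLASSES,
) -> pd.DataFrame:
    """Genome-level DensityRecords per (region class x strand context).

    The denominator for a class is the total bp of the interval union of
    that class over all genes; the numerator counts distinct hits
    overlapping the union (once per class, however many genes they touch).
    The same single-strand span is used for coding and template records.
    """
    spans = class_union_spans(regions)
    rows = []
    for cls in classes:
        span = spans.get(cls, 0)
        sub = assignment[assignment["region_class"] == cls]
        counts = {
            "double": sub["hit_idx"].nunique(),
            "coding": sub.loc[sub["context"] == "coding", "hit_idx"].nunique(),
            "template": sub.loc[sub["context"] == "template", "hit_idx"].nunique(),
        }
        for ctx in CONTEXTS:
            flagged = span <= 0
            if flagged:
                logger.warning("region class %s has zero total span", cls)
            rows.append(
                DensityRecord(cls, ctx, counts[ctx], span, density(counts[ctx], span), flagged)
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def strand_fold(
    coding_density: float, template_density: float, region_class: str = ""
) -> StrandBiasRecord:
    """Fold difference between strand densities (G4SDF), max/min convention."""
    cd, td = coding_density, template_density
    if cd < 0 or td < 0:
        raise ValueError("densities must be >= 0")
    if cd == 0 and td == 0:
        return StrandBiasRecord(region_class, cd, td, float("nan"), "tie", flagged=True)
    if cd == 0 or td == 0:
        dominant = "coding" if cd > td else "template"
        return StrandBiasRecord(region_class, cd, td, float("inf"), dominant, flagged=True)
    if cd == td:
        return StrandBiasRecord(region_class, cd, td, 1.0, "tie")
    g4sdf = max(cd, td) / min(cd, td)
    return StrandBiasRecord(region_class, cd, td, g4sdf, "coding" if cd > td else "template")


def strand_bias_test(coding_count: int, template_count: int) -> float:
    """Exact two-sided binomial p-value for equal-exposure strand counts."""
    n = coding_count + template_count
    if n <= 0:
        return float("nan")
    return float(sps.binomtest(coding_count, n, 0.5, alternative="two-sided").pvalue)


@dataclass
class GeneClassification:
    """Genes binned by per-gene hit count in one region class."""

    cutoff: int
    total_genes: int
    histogram: dict[str, int]
    above_cutoff: list[str]
    proportion_above: float
    proportion_with_any: float

    @property
    def proportions(self) -> dict[str, float]:
        return {k: v / self.total_genes for k, v in self.histogram.items()}


def classify_genes(per_gene_counts: Mapping[str, int], cutoff: int) -> GeneClassification:
    """Bin every annotated gene (zeros included) by hit count.

    ``above_cutoff`` uses a strict ``> cutoff`` inequality; proportions are
    over the whole gene universe.
    """
    if not per_gene_counts:
        raise ValueError("empty gene universe")
    total = len(per_gene_counts)
    hist = {"0": 0, f"1-{cutoff}": 0, f">{cutoff}": 0}
    above = []
    n_any = 0
    for gid, count in per_gene_counts.items():
        if count > 0:
            n_any += 1
        if count == 0:
            hist["0"] += 1
        elif count <= cutoff:
            hist[f"1-{cutoff}"] += 1
        else:
            hist[f">{cutoff}"] += 1
            above.append(gid)
    return GeneClassification(
        cutoff=cutoff,
        total_genes=total,
        histogram=hist,
        above_cutoff=sorted(above),
        proportion_above=len(above) / total,
        proportion_with_any=n_any / total,
    )


GENESET_CLASSES = ("gene", "TSS500", "promoter2000")


def geneset_counts(
    categories: pd.DataFrame,
    gene_class_counts: pd.DataFrame,
    classes: Sequence[str] = GENESET_CLASSES,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-gene and per-category double-strand hit counts for curated gene sets.

    ``categories`` has columns (gene_id, category); ``gene_class_counts`` is
    the per-gene table from :func:`g4scape.annotate.per_gene_counts`.
    Returns (per_gene, per_category, unknown_gene_ids); unknown IDs are
    warned about and listed, not fatal.
    """
    known = set(gene_class_counts["gene_id"])
    unknown = sorted(set(categories["gene_id"]) - known)
    for gid in unknown:
        logger.warning("gene-set member %s not in annotation", gid)
    usable = categories[categories["gene_id"].isin(known)]
    wide = (
        gene_class_counts[gene_class_counts["region_class"].isin(classes)]
        .pivot_table(index="gene_id", columns="region_class", values="double", fill_value=0)
        .reindex(columns=list(classes), fill_value=0)
    )
    per_gene = usable.merge(wide, left_on="gene_id", right_index=True, how="left").fillna(0)
    per_gene[list(classes)] = per_gene[list(classes)].astype(int)
    per_category = per_gene.groupby("category")[list(classes)].sum().reset_index()
    return per_gene, per_category, unknown


CORRELATION_FEATURES = ("gc_percent", "gene_density", "tandem_repeat_density", "te_density")


def chromosome_correlations(
    summaries: pd.DataFrame, features: Sequence[str] = CORRELATION_FEATURES
) -> pd.DataFrame:
    """Pearson r (and two-sided p) of per-chromosome G4 density vs each feature."""
    if len(summaries) < 3:
        raise ValueError(f"need >= 3 chromosomes, got {len(summaries)}")
    y = summaries["g4_density"].to_numpy(dtype=float)
    rows = []
    for feat in features:
        if feat not in summaries.columns:
            continue
        x = summaries[feat].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((feat, float("nan"), float("nan"), True))
            logger.warning("zero variance in %s or g4_density; correlation undefined", feat)
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((feat, float(r), float(p), False))
    return pd.DataFrame(rows, columns=["feature", "pearson_r", "p_value", "flagged"])


def windowed_track(
    hits: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    window_bp: int,
    step: int | None = None,
) -> pd.DataFrame:
    """Per-window hit density; a hit belongs to the window holding its start.

    With ``step == window_bp`` (the default) windows tile each contig and
    per-window counts sum to the total hit count.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    step = step or window_bp
    rows = []
    for seq_id in sorted(contig_lengths):
        clen = contig_lengths[seq_id]
        starts = hits.loc[hits["seq_id"] == seq_id, "start"].to_numpy()
        for ws in range(0, max(clen, 1), step):
            we = min(ws + window_bp, clen)
            if we <= ws:
                break
            n = int(((starts >= ws) & (starts < we)).sum())
            rows.append((seq_id, ws, we, n, density(n, we - ws)))
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "count", "density"])


def write_bedgraph(track: pd.DataFrame, path: str | Path, value_col: str = "density") -> None:
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            fh.write(f"{row.seq_id}\t{row.start}\t{row.end}\t{getattr(row, value_col):.6g}\n")


def subset_counts(
    hits: pd.DataFrame, subsets: pd.DataFrame
) -> pd.DataFrame:
    """Hit count and density inside user-supplied coordinate subsets.

    ``subsets`` columns: seq_id, start, end[, name] (0-based half-open),
    e.g. centromere coordinates. A hit counts when it overlaps the subset
    by >= 1 bp.
    """
    rows = []
    for sub in subsets.itertuples(index=False):
        mask = (
            (hits["seq_id"] == sub.seq_id)
            & (hits["start"] < sub.end)
            & (hits["end"] > sub.start)
        )
        n = int(mask.sum())
        name = getattr(sub, "name", f"{sub.seq_id}:{sub.start}-{sub.end}")
        rows.append((name, sub.seq_id, sub.start, sub.end, n, density(n, sub.end - sub.start)))
    return pd.DataFrame(
        rows, columns=["name", "seq_id", "start", "end", "count", "density"]
    )
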