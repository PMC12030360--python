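"""Strand-aware feature regions from GFF3 and hit-to-region assignment.

Regions derived per gene: the gene body, exon/CDS/UTR unions over the
gene's transcripts, introns (transcript span minus exons), upstream
promoters of 2000/1500/1000/500 bp (strand-aware: upstream of the TSS,
clipped at contig ends) and TSS500, the 500 bp window centred on the
transcription start site (250 bp each side; the TSS base sits in the
downstream half).

A hit overlapping a region of a gene is in "coding" context when its
G-rich strand equals the gene strand (the G tract lies on the sense/mRNA
strand) and "template" context otherwise; "double" is the union of both.
All coordinates are 0-based half-open; GFF3 input (1-based inclusive) is
converted on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("g4scape")

PROMOTER_LENGTHS = (2000, 1500, 1000, 500)
TSS_HALFWIDTH = 250

REGION_CLASSES = (
    "gene",
    "exon",
    "CDS",
    "intron",
    "five_prime_UTR",
    "three_prime_UTR",
    "promoter2000",
    "promoter1500",
    "promoter1000",
    "promoter500",
    "TSS500",
)

CONTEXTS = ("double", "coding", "template")


@dataclass(frozen=True)
class FeatureRegion:
    """One strand-aware annotation interval tied to a gene (0-based half-open)."""

    gene_id: str
    region_class: str
    seq_id: str
    start: int
    end: int
    gene_strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty region {self.region_class} for {self.gene_id}: "
                f"[{self.start},{self.end})"
            )

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    tx_id: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class Gene:
    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class AnnotationStore:
    """Hierarchical gene -> transcript -> subfeature store keyed by gene ID."""

    genes: dict[str, Gene] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and coalesced."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_span(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def _feature_id(feature) -> str | None:
    for key in ("ID", "gene_id", "Name"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def load_annotation(gff_path: str | Path) -> AnnotationStore:
    """Parse a GFF3 file into an :class:`AnnotationStore`.

    Genes without a usable strand are skipped with a warning. 1-based
    inclusive GFF coordinates become 0-based half-open. A gene with no
    mRNA children is given one synthetic transcript spanning the gene
    with a single exon.
    """
    gff_path = Path(gff_path)
    if not gff_path.exists():
        raise FileNotFoundError(f"annotation file not found: {gff_path}")
    try:
        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise ValueError(f"malformed GFF3 {gff_path}: {exc}") from exc

    store = AnnotationStore()
    for gf in db.features_of_type("gene"):
        gid = _feature_id(gf)
        if gid is None:
            logger.warning("gene without ID at %s:%d-%d skipped", gf.seqid, gf.start, gf.end)
            store.skipped.append(f"{gf.seqid}:{gf.start}-{gf.end}")
            continue
        if gf.strand not in ("+", "-"):
            logger.warning("gene %s has no strand; record rejected", gid)
            store.skipped.append(gid)
            continue
        gene = Gene(gid, gf.seqid, gf.start - 1, gf.end, gf.strand)
        for tf in db.children(gf, featuretype=("mRNA", "transcript")):
            tx = Transcript(_feature_id(tf) or f"{gid}.t", tf.start - 1, tf.end)
            for sub in db.children(tf):
                iv = (sub.start - 1, sub.end)
                if sub.featuretype == "exon":
                    tx.exons.append(iv)
                elif sub.featuretype == "CDS":
                    tx.cds.append(iv)
                elif sub.featuretype == "five_prime_UTR":
                    tx.utr5.append(iv)
                elif sub.featuretype == "three_prime_UTR":
                    tx.utr3.append(iv)
            if not tx.exons:
                tx.exons = [(tx.start, tx.end)]
            gene.transcripts.append(tx)
        if not gene.transcripts:
            gene.transcripts.append(
                Transcript(f"{gid}.t", gene.start, gene.end, exons=[(gene.start, gene.end)])
            )
        store.genes[gid] = gene
    return store


def _introns(tx: Transcript) -> list[tuple[int, int]]:
    exons = merge_intervals(tx.exons)
    out = []
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 > e1:
            out.append((e1, s2))
    return out


def tss_position(gene: Gene) -> int:
    """0-based index of the transcription start base (strand-aware)."""
    return gene.start if gene.strand == "+" else gene.end - 1


def derive_regions(
    store: AnnotationStore,
    contig_lengths: Mapping[str, int],
    promoter_lengths: Sequence[int] = PROMOTER_LENGTHS,
    tss_halfwidth: int = TSS_HALFWIDTH,
) -> list[FeatureRegion]:
    """Emit every per-gene region of every class, clipped to the contig.

    Promoters fully clipped away (gene flush against a contig edge) are
    excluded and logged rather than emitted as zero-length markers.
    """
    regions: list[FeatureRegion] = []
    for gene in store.genes.values():
        clen = contig_lengths.get(gene.seq_id)
        if clen is None:
            raise KeyError(f"no contig length for {gene.seq_id} (gene {gene.gene_id})")

        def emit(cls: str, ivs: Iterable[tuple[int, int]]) -> None:
            for s, e in merge_intervals(ivs):
                s, e = max(0, s), min(clen, e)
                if e > s:
                    regions.append(
                        FeatureRegion(gene.gene_id, cls, gene.seq_id, s, e, gene.strand)
                    )
                else:
                    logger.info(
                        "region %s of %s fully clipped at contig edge; excluded",
                        cls,
                        gene.gene_id,
                    )

        emit("gene", [(gene.start, gene.end)])
        emit("exon", (iv for tx in gene.transcripts for iv in tx.exons))
        emit("CDS", (iv for tx in gene.transcripts for iv in tx.cds))
        emit("five_prime_UTR", (iv for tx in gene.transcripts for iv in tx.utr5))
        emit("three_prime_UTR", (iv for tx in gene.transcripts for iv in tx.utr3))
        emit("intron", (iv for tx in gene.transcripts for iv in _introns(tx)))

        for n in promoter_lengths:
            if gene.strand == "+":
                iv = (gene.start - n, gene.start)
            else:
                iv = (gene.end, gene.end + n)
            emit(f"promoter{n}", [iv])

        tss = tss_position(gene)
        if gene.strand == "+":
            emit("TSS500", [(tss - tss_halfwidth, tss + tss_halfwidth)])
        else:
            emit("TSS500", [(tss + 1 - tss_halfwidth, tss + 1 + tss_halfwidth)])
    return regions


def strand_context(hit_strand: str, gene_strand: str) -> str:
    """"coding" when the G-rich strand is the gene's sense strand."""
    return "coding" if hit_strand == gene_strand else "template"


ASSIGNMENT_COLUMNS = ["hit_idx", "seq_id", "gene_id", "region_class", "gene_strand", "context"]


def assign_hits(hits: pd.DataFrame, regions: Sequence[FeatureRegion]) -> pd.DataFrame:
    """Overlap join: one row per (hit, overlapping per-gene region).

    A hit counts in a region when they share >= 1 bp; a hit may hit
    multiple classes and multiple genes.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, reg in enumerate(regions):
        trees.setdefault(reg.seq_id, IntervalTree()).addi(reg.start, reg.end, idx)
    rows = []
    for hit in hits.itertuples():
        tree = trees.get(hit.seq_id)
        if tree is None:
            continue
        for iv in tree.overlap(hit.start, hit.end):
            reg = regions[iv.data]
            rows.append(
                (
                    hit.Index,
                    hit.seq_id,
                    reg.gene_id,
                    reg.region_class,
                    reg.gene_strand,
                    strand_context(hit.strand, reg.gene_strand),
                )
            )
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def class_union_spans(regions: Sequence[FeatureRegion]) -> dict[str, int]:
    """Genome-wide union span (bp) per region class across all genes."""
    by_class: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for reg in regions:
        by_class.setdefault(reg.region_class, {}).setdefault(reg.seq_id, []).append(
            (reg.start, reg.end)
        )
    return {
        cls: sum(total_span(ivs) for ivs in per_seq.values())
        for cls, per_seq in by_class.items()
    }


def per_gene_counts(assignment: pd.DataFrame, gene_ids: Sequence[str]) -> pd.DataFrame:
    """Per (gene, class, context) distinct-hit counts, zero rows included.

    ``double`` counts each distinct hit once per (gene, class).
    """
    rows = []
    if len(assignment):
        grouped = assignment.groupby(["gene_id", "region_class"])
        for (gid, cls), sub in grouped:
            n_double = sub["hit_idx"].nunique()
            n_coding = sub.loc[sub["context"] == "coding", "hit_idx"].nunique()
            n_template = sub.loc[sub["context"] == "template", "hit_idx"].nunique()
            rows.append((gid, cls, n_double, n_coding, n_template))
    counts = pd.DataFrame(
        rows, columns=["gene_id", "region_class", "double", "coding", "template"]
    )
    # reindex over the full gene universe so zero-count genes are present
    full = pd.MultiIndex.from_product(
        [list(gene_ids), list(REGION_CLASSES)], names=["gene_id", "region_class"]
    )
    counts = (
        counts.set_index(["gene_id", "region_class"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    return counts


def write_region_beds(regions: Sequence[FeatureRegion], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_class: dict[str, list[FeatureRegion]] = {}
    for reg in regions:
        by_class.setdefault(reg.region_class, []).append(reg)
    for cls, regs in by_class.items():
        regs.sort(key=lambda r: (r.seq_id, r.start, r.end))
        with open(out_dir / f"{cls}.bed", "w") as fh:
            for r in regs:
                fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.gene_strand}\n")
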