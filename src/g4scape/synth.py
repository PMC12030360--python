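"""Synthetic genomes with planted quadruplex motifs and known ground truth.

The generator emits a small multi-chromosome genome whose background
contains no G or C run of length >= 3 (rejection-resampled), plus planted
copies of a quadruplex motif (default: the telomeric 25-mer, window mean
37/25 = 1.48) at controlled per-kbp densities inside strand-aware gene
zones (promoter, TSS, gene body). Each motif is flanked by window-1 A/T
bases, so a default-parameter scan recovers exactly the planted intervals
— the ground truth is exact, not statistical. Generation finishes with a
verification scan and refuses to emit a dataset where any non-planted hit
appears.

Gene zones are laid out so that every gene's full footprint (gene body plus
2 kb on each flank) fits inside its own slot; genes never overlap and
coding + template counts always partition the double-strand counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import g4scan
from .annotate import (
    AnnotationStore,
    FeatureRegion,
    Gene,
    Transcript,
    derive_regions,
    strand_context,
)
from .g4scan import ScanParams, detect, revcomp

logger = logging.getLogger("g4scape")

TELOMERIC_MOTIF = "GGGTTAGGGTTAGGGTTAGGGTTAG"

_ZONE_MARGIN = 30  # bp kept motif-free at each zone edge
_FLANK = None  # computed from window at plant time


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions of the synthetic genome.

    Densities are per kbp of zone span, split by strand context. Defaults
    emulate the grapevine-scale regulatory structure: TSS-centred windows at
    ~1.0/kbp with near-equal strands, promoters at ~0.54/kbp with a coding
    bias, gene bodies with a 2.45:1 coding:template ratio, and drought-style
    DEG groups whose TSS windows carry a 3:1 strand bias (template-dominant
    for upregulated genes, coding-dominant for downregulated ones).
    """

    n_chromosomes: int = 3
    chrom_length: int = 300_000
    gc_fraction: float = 0.35
    genes_per_chromosome: int = 40
    gene_length: int = 3000
    p_plus_strand: float = 0.5
    motif: str = TELOMERIC_MOTIF
    tss_density: Mapping[str, float] = field(
        default_factory=lambda: {"coding": 0.5, "template": 0.5}
    )
    promoter_density: Mapping[str, float] = field(
        default_factory=lambda: {"coding": 0.36, "template": 0.18}
    )
    gene_body_density: Mapping[str, float] = field(
        default_factory=lambda: {"coding": 0.6125, "template": 0.25}
    )
    n_up: int = 30
    n_down: int = 30
    deg_tss_counts_up: Mapping[str, int] = field(
        default_factory=lambda: {"coding": 1, "template": 3}
    )
    deg_tss_counts_down: Mapping[str, int] = field(
        default_factory=lambda: {"coding": 3, "template": 1}
    )
    n_high_promoter: int = 5
    high_promoter_counts: Mapping[str, int] = field(
        default_factory=lambda: {"coding": 8, "template": 4}
    )
    n_high_tss: int = 5
    high_tss_counts: Mapping[str, int] = field(
        default_factory=lambda: {"coding": 3, "template": 3}
    )
    timepoint: str = "D2"
    scan: ScanParams = field(default_factory=ScanParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_length < 2100:
            raise ValueError("gene_length must be >= 2100 (UTR/exon layout)")
        for dens in (self.tss_density, self.promoter_density, self.gene_body_density):
            if any(v < 0 for v in dens.values()):
                raise ValueError("densities must be >= 0")
        mean = float(np.mean(g4scan.base_scores(self.motif, self.scan.run_cap)))
        if mean < self.scan.threshold:
            raise ValueError(
                f"motif window mean {mean:.3f} below threshold {self.scan.threshold}"
            )
        slot = self.chrom_length // self.genes_per_chromosome
        if slot < self.gene_length + 4000 + 400:
            raise ValueError("chromosome too short for the requested gene layout")


@dataclass
class GroundTruth:
    """What was planted, in pipeline-comparable form."""

    hits: pd.DataFrame  # seq_id, start, end, strand, gene_id, zone, context
    per_gene_counts: pd.DataFrame  # gene_id, region_class, double, coding, template
    deg_labels: pd.DataFrame  # gene_id, direction, timepoint
    group_ratio: dict[str, float]
    high_promoter_genes: list[str]
    high_tss_genes: list[str]


@dataclass
class SynthDataset:
    spec: SynthSpec
    sequences: dict[str, str]
    store: AnnotationStore
    gff_text: str
    deg_table: pd.DataFrame
    truth: GroundTruth

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sequences.items()}

    def fasta_text(self, width: int = 80) -> str:
        chunks = []
        for name in sorted(self.sequences):
            seq = self.sequences[name]
            chunks.append(f">{name}\n")
            chunks.extend(seq[i : i + width] + "\n" for i in range(0, len(seq), width))
        return "".join(chunks)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out_dir / "genome.fa",
            "gff": out_dir / "annotation.gff3",
            "deg": out_dir / f"deg_{self.spec.timepoint}.tsv",
            "truth_hits": out_dir / "truth_hits.tsv",
            "truth_counts": out_dir / "truth_gene_counts.tsv",
            "truth_labels": out_dir / "truth_deg_labels.tsv",
        }
        paths["fasta"].write_text(self.fasta_text())
        paths["gff"].write_text(self.gff_text)
        self.deg_table.to_csv(paths["deg"], sep="\t", index=False)
        self.truth.hits.to_csv(paths["truth_hits"], sep="\t", index=False)
        self.truth.per_gene_counts.to_csv(paths["truth_counts"], sep="\t", index=False)
        self.truth.deg_labels.to_csv(paths["truth_labels"], sep="\t", index=False)
        return paths


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AT = np.frombuffer(b"AT", dtype=np.uint8)
_G, _C = ord("G"), ord("C")


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = _BASES[rng.choice(4, size=n, p=p)]
    # break any G/C run of length >= 3 by rewriting its third base to A/T
    while True:
        third = (
            (arr[2:] == arr[1:-1])
            & (arr[1:-1] == arr[:-2])
            & ((arr[2:] == _G) | (arr[2:] == _C))
        )
        idx = np.flatnonzero(third) + 2
        if idx.size == 0:
            return arr
        arr[idx] = _AT[rng.integers(0, 2, size=idx.size)]


@dataclass
class _GeneLayout:
    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str

    def zone(self, name: str) -> tuple[int, int]:
        gs, ge = self.start, self.end
        if self.strand == "+":
            return {
                "tss": (gs - 250, gs + 250),
                "promoter": (gs - 2000, gs - 250),
                "body": (gs + 250, ge),
            }[name]
        return {
            "tss": (ge - 250, ge + 250),
            "promoter": (ge + 250, ge + 2000),
            "body": (gs, ge - 250),
        }[name]


def _motif_slots(zone: tuple[int, int], motif_len: int, window: int) -> list[int]:
    lo = zone[0] + _ZONE_MARGIN
    hi = zone[1] - _ZONE_MARGIN - motif_len
    stride = motif_len + window + 10
    return list(range(lo, hi + 1, stride))


class _Quota:
    """Largest-remainder accumulator: total planted count tracks density * span."""

    def __init__(self) -> None:
        self.acc: dict[tuple, float] = {}

    def take(self, key: tuple, increment: float) -> int:
        prev = self.acc.get(key, 0.0)
        new = prev + increment
        n = int(math.floor(new + 1e-9)) - int(math.floor(prev + 1e-9))
        self.acc[key] = new
        return n


def _build_store(layouts: list[_GeneLayout], gene_length: int) -> AnnotationStore:
    store = AnnotationStore()
    for g in layouts:
        gs, ge = g.start, g.end
        exons = [(gs, gs + 1200), (gs + 1800, ge)]
        cds = [(gs + 150, gs + 1200), (gs + 1800, ge - 150)]
        if g.strand == "+":
            utr5, utr3 = [(gs, gs + 150)], [(ge - 150, ge)]
        else:
            utr5, utr3 = [(ge - 150, ge)], [(gs, gs + 150)]
        tx = Transcript(f"{g.gene_id}.1", gs, ge, exons=exons, cds=cds, utr5=utr5, utr3=utr3)
        store.genes[g.gene_id] = Gene(g.gene_id, g.seq_id, gs, ge, g.strand, [tx])
    return store


def _gff_text(store: AnnotationStore, contig_lengths: Mapping[str, int]) -> str:
    lines = ["##gff-version 3"]
    for seq_id in sorted(contig_lengths):
        lines.append(f"##sequence-region {seq_id} 1 {contig_lengths[seq_id]}")
    for gid in sorted(store.genes):
        g = store.genes[gid]
        lines.append(
            f"{g.seq_id}\tg4scape_synth\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={gid}"
        )
        for tx in g.transcripts:
            lines.append(
                f"{g.seq_id}\tg4scape_synth\tmRNA\t{tx.start + 1}\t{tx.end}\t.\t{g.strand}\t.\t"
                f"ID={tx.tx_id};Parent={gid}"
            )
            for ftype, ivs in (
                ("exon", tx.exons),
                ("CDS", tx.cds),
                ("five_prime_UTR", tx.utr5),
                ("three_prime_UTR", tx.utr3),
            ):
                for k, (s, e) in enumerate(ivs, start=1):
                    phase = "0" if ftype == "CDS" else "."
                    lines.append(
                        f"{g.seq_id}\tg4scape_synth\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                        f"ID={tx.tx_id}.{ftype}{k};Parent={tx.tx_id}"
                    )
    return "\n".join(lines) + "\n"


def _truth_gene_counts(
    hits: pd.DataFrame, regions: list[FeatureRegion], gene_ids: list[str]
) -> pd.DataFrame:
    """Direct interval arithmetic: planted hits vs per-gene regions."""
    from .annotate import REGION_CLASSES

    counts: dict[tuple[str, str], dict[str, set[int]]] = {}
    for reg in regions:
        key = (reg.gene_id, reg.region_class)
        slot = counts.setdefault(key, {"double": set(), "coding": set(), "template": set()})
        for hit in hits.itertuples():
            if hit.seq_id != reg.seq_id or hit.start >= reg.end or hit.end <= reg.start:
                continue
            slot["double"].add(hit.Index)
            slot[strand_context(hit.strand, reg.gene_strand)].add(hit.Index)
    rows = []
    for gid in gene_ids:
        for cls in REGION_CLASSES:
            slot = counts.get((gid, cls), {"double": set(), "coding": set(), "template": set()})
            rows.append((gid, cls, len(slot["double"]), len(slot["coding"]), len(slot["template"])))
    return pd.DataFrame(rows, columns=["gene_id", "region_class", "double", "coding", "template"])


def _deg_table(
    rng: np.random.Generator, gene_ids: list[str], labels: Mapping[str, str]
) -> pd.DataFrame:
    rows = []
    for gid in gene_ids:
        direction = labels.get(gid, "ns")
        if direction == "up":
            lfc = round(float(rng.uniform(1.0, 5.0)), 4)
            padj = float(10 ** -rng.uniform(2, 8))
        elif direction == "down":
            lfc = -round(float(rng.uniform(1.0, 5.0)), 4)
            padj = float(10 ** -rng.uniform(2, 8))
        else:
            u = rng.random()
            if u < 0.05:
                lfc = round(float(rng.uniform(-3, 3)), 4)
                padj = float("nan")
            elif u < 0.5:
                lfc = round(float(rng.uniform(-0.95, 0.95)), 4)
                padj = float(rng.uniform(0.0, 1.0))
            else:
                lfc = round(float(rng.uniform(-4, 4)), 4)
                padj = float(rng.uniform(0.06, 1.0))
        rows.append((gid, lfc, padj))
    return pd.DataFrame(rows, columns=["gene_id", "log2FoldChange", "padj"])


def generate(spec: SynthSpec, out_dir: str | Path | None = None, verify: bool = True) -> SynthDataset:
    """Build the synthetic dataset; optionally write it to ``out_dir``.

    Raises if a requested planted count does not fit the zone (names the
    limiting region) or, with ``verify=True``, if a scan at the spec's
    parameters finds anything other than the planted hits.
    """
    rng = np.random.default_rng(spec.seed)
    motif = spec.motif.upper()
    mlen = len(motif)
    window = spec.scan.window
    flank = window - 1

    # -- gene layout ------------------------------------------------------
    layouts: list[_GeneLayout] = []
    slot = spec.chrom_length // spec.genes_per_chromosome
    for c in range(spec.n_chromosomes):
        seq_id = f"chr{c + 1}"
        for i in range(spec.genes_per_chromosome):
            gid = f"g{c * spec.genes_per_chromosome + i + 1:04d}"
            gs = i * slot + 2250
            layouts.append(_GeneLayout(gid, seq_id, gs, gs + spec.gene_length,
                                       "+" if rng.random() < spec.p_plus_strand else "-"))
    gene_ids = [g.gene_id for g in layouts]

    # -- role assignment (disjoint) ---------------------------------------
    n_special = spec.n_up + spec.n_down + spec.n_high_promoter + spec.n_high_tss
    if n_special > len(gene_ids):
        raise ValueError("more special genes requested than genes available")
    picked = [str(g) for g in rng.permutation(gene_ids)[:n_special]]
    up_genes = sorted(picked[: spec.n_up])
    down_genes = sorted(picked[spec.n_up : spec.n_up + spec.n_down])
    rest = picked[spec.n_up + spec.n_down :]
    high_prom = sorted(rest[: spec.n_high_promoter])
    high_tss = sorted(rest[spec.n_high_promoter :])
    labels = {g: "up" for g in up_genes} | {g: "down" for g in down_genes}

    # -- choose planted motif positions -----------------------------------
    zone_density = {
        "tss": spec.tss_density,
        "promoter": spec.promoter_density,
        "body": spec.gene_body_density,
    }
    quota = _Quota()
    planted: list[tuple[str, int, int, str, str, str, str]] = []

    def plant(g: _GeneLayout, zone_name: str, wanted: Mapping[str, int]) -> None:
        zone = g.zone(zone_name)
        slots = _motif_slots(zone, mlen, window)
        total = sum(wanted.values())
        if total > len(slots):
            raise ValueError(
                f"requested density infeasible: {total} motifs do not fit the "
                f"{zone_name} zone of gene {g.gene_id} ({len(slots)} slots)"
            )
        order = rng.permutation(len(slots))[:total]
        contexts = ["coding"] * wanted.get("coding", 0) + ["template"] * wanted.get("template", 0)
        for pos_idx, ctx in zip(order, contexts):
            p = slots[pos_idx]
            hit_strand = g.strand if ctx == "coding" else ("-" if g.strand == "+" else "+")
            planted.append((g.seq_id, p, p + mlen, hit_strand, g.gene_id, zone_name, ctx))

    for g in layouts:
        # TSS zone: fixed counts for special genes, density-driven otherwise
        if g.gene_id in labels:
            wanted = (
                spec.deg_tss_counts_up if labels[g.gene_id] == "up" else spec.deg_tss_counts_down
            )
            plant(g, "tss", wanted)
        elif g.gene_id in high_tss:
            plant(g, "tss", spec.high_tss_counts)
        else:
            span = g.zone("tss")[1] - g.zone("tss")[0]
            wanted = {
                ctx: quota.take(("tss", ctx), d * span / 1000.0)
                for ctx, d in spec.tss_density.items()
            }
            plant(g, "tss", wanted)
        if g.gene_id in high_prom:
            plant(g, "promoter", spec.high_promoter_counts)
        else:
            span = g.zone("promoter")[1] - g.zone("promoter")[0]
            wanted = {
                ctx: quota.take(("promoter", ctx), d * span / 1000.0)
                for ctx, d in spec.promoter_density.items()
            }
            plant(g, "promoter", wanted)
        span = g.zone("body")[1] - g.zone("body")[0]
        wanted = {
            ctx: quota.take(("body", ctx), d * span / 1000.0)
            for ctx, d in spec.gene_body_density.items()
        }
        plant(g, "body", wanted)

    # -- assemble sequences ------------------------------------------------
    fwd = np.frombuffer(motif.encode(), dtype=np.uint8)
    rev = np.frombuffer(revcomp(motif).encode(), dtype=np.uint8)
    sequences: dict[str, str] = {}
    for c in range(spec.n_chromosomes):
        seq_id = f"chr{c + 1}"
        arr = _background(rng, spec.chrom_length, spec.gc_fraction)
        for sid, s, e, strand, *_ in planted:
            if sid != seq_id:
                continue
            arr[s:e] = fwd if strand == "+" else rev
            lo, hi = max(0, s - flank), min(arr.size, e + flank)
            arr[lo:s] = _AT[rng.integers(0, 2, size=s - lo)]
            arr[e:hi] = _AT[rng.integers(0, 2, size=hi - e)]
        sequences[seq_id] = arr.tobytes().decode("ascii")

    hits_df = pd.DataFrame(
        sorted(planted), columns=["seq_id", "start", "end", "strand", "gene_id", "zone", "context"]
    )

    # -- annotation, truth, DEG table --------------------------------------
    store = _build_store(layouts, spec.gene_length)
    contig_lengths = {k: len(v) for k, v in sequences.items()}
    gff_text = _gff_text(store, contig_lengths)
    regions = derive_regions(store, contig_lengths)
    per_gene = _truth_gene_counts(hits_df, regions, sorted(gene_ids))
    deg_labels = pd.DataFrame(
        [(gid, labels.get(gid, "ns"), spec.timepoint) for gid in sorted(gene_ids)],
        columns=["gene_id", "direction", "timepoint"],
    )
    up_counts = spec.deg_tss_counts_up
    down_counts = spec.deg_tss_counts_down
    truth = GroundTruth(
        hits=hits_df,
        per_gene_counts=per_gene,
        deg_labels=deg_labels,
        group_ratio={
            "up": max(up_counts.values()) / min(up_counts.values()),
            "down": max(down_counts.values()) / min(down_counts.values()),
        },
        high_promoter_genes=high_prom,
        high_tss_genes=high_tss,
    )
    deg_table = _deg_table(rng, sorted(gene_ids), labels)

    dataset = SynthDataset(spec, sequences, store, gff_text, deg_table, truth)

    if verify:
        expected = {
            (r.seq_id, r.start, r.end, r.strand) for r in hits_df.itertuples(index=False)
        }
        found = set()
        for seq_id, seq in sequences.items():
            for h in detect(seq, spec.scan, seq_id=seq_id):
                found.add((h.seq_id, h.start, h.end, h.strand))
        if found != expected:
            raise RuntimeError(
                f"synthetic genome verification failed: {len(found - expected)} spurious, "
                f"{len(expected - found)} missing hit(s)"
            )

    if out_dir is not None:
        dataset.write(out_dir)
    return dataset


def perturb(dataset: SynthDataset, fraction: float, seed: int | None = None) -> SynthDataset:
    """Point-mutate the central base of a fraction of planted motifs.

    A central G becomes T (central C becomes A on minus-strand copies),
    breaking the middle G-tract; refined scores drop and the hit count is
    non-increasing in ``fraction``. Ground truth is carried over unchanged
    (it describes the planted, unperturbed coordinates).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(dataset.spec.seed + 7919 if seed is None else seed)
    hits = dataset.truth.hits
    n_mut = int(round(fraction * len(hits)))
    chosen = set(rng.permutation(len(hits))[:n_mut].tolist())
    arrays = {
        sid: np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        for sid, seq in dataset.sequences.items()
    }
    for i, hit in enumerate(hits.itertuples(index=False)):
        if i not in chosen:
            continue
        center = hit.start + (hit.end - hit.start) // 2
        arr = arrays[hit.seq_id]
        if arr[center] == _G:
            arr[center] = ord("T")
        elif arr[center] == _C:
            arr[center] = ord("A")
        else:
            logger.warning("motif at %s:%d has no central G/C; left unmutated", hit.seq_id, hit.start)
    sequences = {sid: arr.tobytes().decode("ascii") for sid, arr in arrays.items()}
    return SynthDataset(
        dataset.spec, sequences, dataset.store, dataset.gff_text, dataset.deg_table, dataset.truth
    )
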