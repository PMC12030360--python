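"""End-to-end orchestration: scan -> annotate -> stats -> DEG overlay.

One run writes a stage-per-subfolder output directory (scan/, regions/,
stats/, degs/) plus a JSON manifest recording the package version, every
parameter, and SHA-256 checksums of inputs and non-log outputs, so a rerun
with the same config is byte-reproducible and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from . import annotate, degset, g4scan, stats
from .g4scan import ScanParams

logger = logging.getLogger("g4scape")


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the offending file."""

    def __init__(self, stage: str, path: object, message: str):
        super().__init__(f"[stage {stage}] {path}: {message}")
        self.stage = stage
        self.path = str(path)


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    The defaults are the published parameterization: window 25 / threshold
    1.2 scanning, promoters {2000,1500,1000,500}, TSS half-width 250,
    |log2FC| >= 1 and padj <= 0.05 for DEGs, strand-fold cutoff 3, and
    gene-classification cutoffs 10 (promoter2000) / 5 (TSS500).
    """

    fasta: str = ""
    gff: str = ""
    out_dir: str = "g4scape_run"
    scan: ScanParams = field(default_factory=ScanParams)
    promoter_lengths: tuple[int, ...] = annotate.PROMOTER_LENGTHS
    tss_halfwidth: int = annotate.TSS_HALFWIDTH
    deg_tables: dict[str, str] = field(default_factory=dict)  # timepoint -> TSV path
    lfc_cut: float = 1.0
    padj_cut: float = 0.05
    fold_cutoff: float = 3.0
    fold_region: str = "TSS500"
    promoter_cutoff: int = 10
    tss_cutoff: int = 5
    centromeres: str | None = None  # TSV: seq_id, start, end[, name]
    tandem_repeats: str | None = None  # BED
    transposable_elements: str | None = None  # BED
    genesets: str | None = None  # TSV: gene_id, category
    track_window: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lfc_cut", "fold_cutoff", "promoter_cutoff", "tss_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scan_kwargs = raw.pop("scan", {})
        cfg = cls(**raw)
        if scan_kwargs:
            cfg.scan = ScanParams(**scan_kwargs)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["promoter_lengths"] = list(self.promoter_lengths)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_bed_counts(path: str, contig_lengths: Mapping[str, int]) -> dict[str, int]:
    counts: dict[str, int] = {k: 0 for k in contig_lengths}
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0], names=["seq_id"], comment="#")
    for sid, n in df["seq_id"].value_counts().items():
        if sid in counts:
            counts[sid] = int(n)
    return counts


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    # ---- stage: scan ------------------------------------------------------
    stage = "scan"
    fasta = Path(config.fasta)
    if not fasta.exists():
        raise PipelineError(stage, fasta, "FASTA not found")
    try:
        hits, summary = g4scan.scan_fasta(fasta, config.scan)
    except Exception as exc:
        raise PipelineError(stage, fasta, str(exc)) from exc
    scan_dir = out / "scan"
    scan_dir.mkdir(exist_ok=True)
    g4scan.write_bed(hits, scan_dir / "hits.bed")
    g4scan.write_hits_tsv(hits, scan_dir / "hits.tsv")
    g4scan.write_summary_tsv(summary, scan_dir / "summary.tsv")
    contig_lengths = dict(zip(summary["seq_id"], summary["length"]))

    # ---- stage: annotate --------------------------------------------------
    stage = "annotate"
    gff = Path(config.gff)
    if not gff.exists():
        raise PipelineError(stage, gff, "GFF3 not found")
    try:
        store = annotate.load_annotation(gff)
        regions = annotate.derive_regions(
            store, contig_lengths, config.promoter_lengths, config.tss_halfwidth
        )
        assignment = annotate.assign_hits(hits, regions)
        gene_counts = annotate.per_gene_counts(assignment, sorted(store.genes))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, gff, str(exc)) from exc
    annotate.write_region_beds(regions, out / "regions")
    gene_counts.to_csv(out / "regions" / "gene_counts.tsv", sep="\t", index=False)

    # ---- stage: stats -----------------------------------------------------
    stage = "stats"
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    try:
        dens = stats.region_densities(assignment, regions)
        dens.to_csv(stats_dir / "densities.tsv", sep="\t", index=False)

        bias_rows = []
        for cls in annotate.REGION_CLASSES:
            sub = dens[dens["region_class"] == cls].set_index("context")
            rec = stats.strand_fold(
                float(sub.loc["coding", "density"]),
                float(sub.loc["template", "density"]),
                region_class=cls,
            )
            p = stats.strand_bias_test(
                int(sub.loc["coding", "hit_count"]), int(sub.loc["template", "hit_count"])
            )
            bias_rows.append({**rec.__dict__, "p_value": p})
        pd.DataFrame(bias_rows).to_csv(stats_dir / "strand_bias.tsv", sep="\t", index=False)

        for cls, cutoff, tag in (
            ("promoter2000", config.promoter_cutoff, "promoter2000"),
            ("TSS500", config.tss_cutoff, "TSS500"),
        ):
            sub = gene_counts[gene_counts["region_class"] == cls]
            counts_map = dict(zip(sub["gene_id"], sub["double"]))
            cl = stats.classify_genes(counts_map, cutoff)
            pd.DataFrame(
                {
                    "bin": list(cl.histogram),
                    "n_genes": list(cl.histogram.values()),
                    "proportion": [cl.proportions[b] for b in cl.histogram],
                }
            ).to_csv(stats_dir / f"classification_{tag}.tsv", sep="\t", index=False)
            (stats_dir / f"genes_above_cutoff_{tag}.txt").write_text(
                "".join(g + "\n" for g in cl.above_cutoff)
            )

        track = stats.windowed_track(hits, contig_lengths, config.track_window)
        stats.write_bedgraph(track, stats_dir / "g4_density.bedgraph")

        gene_count_per_chrom = {
            sid: sum(1 for g in store.genes.values() if g.seq_id == sid)
            for sid in contig_lengths
        }
        chrom = summary.rename(columns={"density_per_kbp": "g4_density"}).copy()
        chrom["gene_density"] = [
            stats.density(gene_count_per_chrom.get(s, 0), l)
            for s, l in zip(chrom["seq_id"], chrom["length"])
        ]
        for col, path in (
            ("tandem_repeat_density", config.tandem_repeats),
            ("te_density", config.transposable_elements),
        ):
            if path:
                counts = _read_bed_counts(path, contig_lengths)
                chrom[col] = [
                    stats.density(counts.get(s, 0), l)
                    for s, l in zip(chrom["seq_id"], chrom["length"])
                ]
        chrom.to_csv(stats_dir / "chromosome_summary.tsv", sep="\t", index=False)
        if len(chrom) >= 3:
            stats.chromosome_correlations(chrom).to_csv(
                stats_dir / "correlations.tsv", sep="\t", index=False
            )

        if config.centromeres:
            cents = pd.read_csv(config.centromeres, sep="\t")
            stats.subset_counts(hits, cents).to_csv(
                stats_dir / "centromeres.tsv", sep="\t", index=False
            )
        if config.genesets:
            cats = pd.read_csv(config.genesets, sep="\t")
            per_gene, per_cat, unknown = stats.geneset_counts(cats, gene_counts)
            per_gene.to_csv(stats_dir / "geneset_gene_counts.tsv", sep="\t", index=False)
            per_cat.to_csv(stats_dir / "geneset_category_counts.tsv", sep="\t", index=False)
            if unknown:
                (stats_dir / "geneset_unknown_ids.txt").write_text(
                    "".join(g + "\n" for g in unknown)
                )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, stats_dir, str(exc)) from exc

    # ---- stage: degs ------------------------------------------------------
    stage = "degs"
    for timepoint, deg_path in sorted(config.deg_tables.items()):
        if not Path(deg_path).exists():
            raise PipelineError(stage, deg_path, "DEG table not found")
        try:
            table = degset.read_deg_table(deg_path)
            classified = degset.filter_degs(table, config.lfc_cut, config.padj_cut, timepoint)
            deg_dir = out / "degs" / timepoint
            deg_dir.mkdir(parents=True, exist_ok=True)
            classified.to_csv(deg_dir / "classified.tsv", sep="\t", index=False)
            for direction in ("up", "down"):
                genes = sorted(classified.loc[classified["direction"] == direction, "gene_id"])
                (deg_dir / f"{direction}.txt").write_text("".join(g + "\n" for g in genes))
                gd = degset.group_densities(genes, assignment, regions)
                gd.to_csv(deg_dir / f"densities_{direction}.tsv", sep="\t", index=False)
                per_gene = degset.per_gene_strand_densities(
                    gene_counts[gene_counts["gene_id"].isin(genes)],
                    regions,
                    config.fold_region,
                )
                sel = degset.select_by_fold(
                    per_gene, config.fold_region, config.fold_cutoff, timepoint, direction
                )
                (deg_dir / f"selection_{direction}.txt").write_text(
                    "".join(g + "\n" for g in sel.selected)
                )
                fold_rows = []
                sub = gd[gd["region_class"] == config.fold_region].set_index("context")
                rec = stats.strand_fold(
                    float(sub.loc["coding", "density"]),
                    float(sub.loc["template", "density"]),
                    region_class=config.fold_region,
                )
                fold_rows.append({**rec.__dict__, "direction": direction})
                pd.DataFrame(fold_rows).to_csv(
                    deg_dir / f"g4sdf_{direction}.tsv", sep="\t", index=False
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, deg_path, str(exc)) from exc

    # ---- manifest ---------------------------------------------------------
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            checksums[str(p.relative_to(out))] = _sha256(p)
    inputs = {"fasta": str(fasta), "gff": str(gff), **config.deg_tables}
    manifest = {
        "g4scape_version": __version__,
        "parameters": config.to_dict(),
        "input_checksums": {k: _sha256(Path(v)) for k, v in inputs.items() if Path(v).exists()},
        "output_checksums": checksums,
        "n_hits": int(len(hits)),
        "n_genes": len(store.genes),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
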