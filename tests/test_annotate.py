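"""Region derivation, coordinate conventions and strand-context assignment."""

from __future__ import annotations

import pandas as pd
import pytest

from g4scape import (
    FeatureRegion,
    assign_hits,
    derive_regions,
    load_annotation,
    per_gene_counts,
    strand_context,
)
from g4scape.annotate import class_union_spans, merge_intervals


GFF = """##gff-version 3
##sequence-region chr1 1 10000
chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tID=g1.t1.e1;Parent=g1.t1
chr1\tsrc\texon\t1501\t2000\t.\t+\t.\tID=g1.t1.e2;Parent=g1.t1
chr1\tsrc\tgene\t5001\t6000\t.\t-\t.\tID=g2
chr1\tsrc\tmRNA\t5001\t6000\t.\t-\t.\tID=g2.t1;Parent=g2
chr1\tsrc\texon\t5001\t6000\t.\t-\t.\tID=g2.t1.e1;Parent=g2.t1
chr1\tsrc\tgene\t8001\t9000\t.\t.\t.\tID=g3
"""


@pytest.fixture()
def store(tmp_path):
    gff = tmp_path / "toy.gff3"
    gff.write_text(GFF)
    return load_annotation(gff)


def test_gff_coordinates_become_zero_based_half_open(store):
    g1 = store.genes["g1"]
    assert (g1.start, g1.end, g1.strand) == (1000, 2000, "+")
    assert g1.transcripts[0].exons == [(1000, 1200), (1500, 2000)]


def test_strandless_gene_is_rejected_with_warning(store):
    assert "g3" not in store.genes
    assert "g3" in store.skipped


def test_intron_is_gap_between_exons(store):
    regions = derive_regions(store, {"chr1": 10_000})
    introns = [(r.start, r.end) for r in regions if r.region_class == "intron" and r.gene_id == "g1"]
    assert introns == [(1200, 1500)]
    # single-exon gene has no introns
    assert not [r for r in regions if r.region_class == "intron" and r.gene_id == "g2"]


def test_promoters_are_upstream_and_clipped(store):
    regions = derive_regions(store, {"chr1": 10_000})
    by = {(r.gene_id, r.region_class): (r.start, r.end) for r in regions}
    assert by[("g1", "promoter2000")] == (0, 1000)  # clipped from nominal -1000
    assert by[("g1", "promoter500")] == (500, 1000)
    assert by[("g2", "promoter500")] == (6000, 6500)  # minus strand: downstream in genome coords
    assert by[("g2", "promoter2000")] == (6000, 8000)


def test_tss500_is_250_each_side_of_the_start_site(store):
    regions = derive_regions(store, {"chr1": 10_000})
    by = {(r.gene_id, r.region_class): (r.start, r.end) for r in regions}
    assert by[("g1", "TSS500")] == (750, 1250)
    assert by[("g2", "TSS500")] == (5750, 6250)


def test_every_region_lies_within_the_contig(store):
    clen = 10_000
    for r in derive_regions(store, {"chr1": clen}):
        assert 0 <= r.start < r.end <= clen


def test_promoter_nesting_is_monotone(store):
    regions = derive_regions(store, {"chr1": 10_000})
    for gid in ("g1", "g2"):
        by = {r.region_class: (r.start, r.end) for r in regions if r.gene_id == gid}
        for small, big in (("promoter500", "promoter1000"), ("promoter1000", "promoter1500"),
                           ("promoter1500", "promoter2000")):
            s, b = by[small], by[big]
            assert b[0] <= s[0] and s[1] <= b[1]


@pytest.mark.parametrize(
    "hit_strand,gene_strand,expected",
    [("+", "+", "coding"), ("-", "+", "template"), ("-", "-", "coding"), ("+", "-", "template")],
)
def test_strand_context_rule(hit_strand, gene_strand, expected):
    assert strand_context(hit_strand, gene_strand) == expected


def test_merge_intervals_union_and_span():
    assert merge_intervals([(5, 10), (0, 6), (20, 30), (10, 12)]) == [(0, 12), (20, 30)]
    spans = class_union_spans(
        [
            FeatureRegion("a", "promoter500", "chr1", 0, 400, "+"),
            FeatureRegion("b", "promoter500", "chr1", 200, 600, "+"),
        ]
    )
    assert spans["promoter500"] == 600  # overlap counted once


def _hits_frame(rows):
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "strand"])


def test_assign_hits_overlap_and_context(store):
    regions = derive_regions(store, {"chr1": 10_000})
    hits = _hits_frame(
        [
            ("chr1", 990, 1015, "+"),   # spans promoter/gene boundary of g1: both classes
            ("chr1", 5900, 5925, "+"),  # inside g2 (minus strand): template context
            ("chr1", 3000, 3025, "+"),  # intergenic
        ]
    )
    asg = assign_hits(hits, regions)
    g1_classes = set(asg.loc[asg["gene_id"] == "g1", "region_class"])
    assert {"gene", "promoter500", "promoter2000", "TSS500", "exon"} <= g1_classes
    ctx = asg.loc[(asg["gene_id"] == "g2") & (asg["region_class"] == "gene"), "context"]
    assert set(ctx) == {"template"}
    assert 2 not in set(asg["hit_idx"])  # intergenic hit assigned nowhere


def test_per_gene_counts_include_zero_genes_and_partition_contexts(store):
    regions = derive_regions(store, {"chr1": 10_000})
    hits = _hits_frame([("chr1", 1600, 1625, "+"), ("chr1", 1700, 1725, "-")])
    counts = per_gene_counts(assign_hits(hits, regions), sorted(store.genes))
    gene_row = counts[(counts["gene_id"] == "g1") & (counts["region_class"] == "gene")].iloc[0]
    assert (gene_row["double"], gene_row["coding"], gene_row["template"]) == (2, 1, 1)
    g2 = counts[(counts["gene_id"] == "g2") & (counts["region_class"] == "gene")].iloc[0]
    assert g2["double"] == 0
    assert (counts["coding"] + counts["template"] == counts["double"]).all()


def test_flipping_gene_strands_swaps_contexts(store):
    regions = derive_regions(store, {"chr1": 10_000})
    flipped = [
        FeatureRegion(r.gene_id, r.region_class, r.seq_id, r.start, r.end,
                      "+" if r.gene_strand == "-" else "-")
        for r in regions
    ]
    hits = _hits_frame([("chr1", 1600, 1625, "+"), ("chr1", 1700, 1725, "-")])
    a = assign_hits(hits, regions).sort_values(["hit_idx", "region_class"]).reset_index()
    b = assign_hits(hits, flipped).sort_values(["hit_idx", "region_class"]).reset_index()
    swap = {"coding": "template", "template": "coding"}
    assert b["context"].tolist() == [swap[c] for c in a["context"]]
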