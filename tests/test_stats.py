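"""Density arithmetic, strand bias, classification, correlations, tracks."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from g4scape import (
    chromosome_correlations,
    classify_genes,
    density,
    geneset_counts,
    strand_bias_test,
    strand_fold,
    windowed_track,
)
from g4scape.stats import subset_counts


@pytest.mark.parametrize(
    "count,span,expected_2dp",
    [
        (26_041, 27_822_162, 0.94),  # published chromosome PN1 profile
        (1_092, 774_663, 1.41),      # published mitochondrial profile
        (0, 5_000, 0.0),
    ],
)
def test_density_per_kbp(count, span, expected_2dp):
    assert round(density(count, span), 2) == expected_2dp


def test_density_zero_span_is_nan():
    assert math.isnan(density(5, 0))


@pytest.mark.parametrize(
    "cd,td,fold,dominant",
    [(0.2, 0.6, 3.0, "template"), (0.5, 0.5, 1.0, "tie"), (0.9, 0.3, 3.0, "coding")],
)
def test_strand_fold_max_min_convention(cd, td, fold, dominant):
    rec = strand_fold(cd, td)
    assert rec.g4sdf == pytest.approx(fold)
    assert rec.dominant == dominant and not rec.flagged


def test_strand_fold_symmetry_and_degenerate_cases():
    a, b = strand_fold(0.2, 0.7), strand_fold(0.7, 0.2)
    assert a.g4sdf == b.g4sdf >= 1.0
    assert {a.dominant, b.dominant} == {"coding", "template"}
    one_zero = strand_fold(0.4, 0.0)
    assert math.isinf(one_zero.g4sdf) and one_zero.dominant == "coding" and one_zero.flagged
    both_zero = strand_fold(0.0, 0.0)
    assert math.isnan(both_zero.g4sdf) and both_zero.flagged


def test_strand_bias_binomial_pvalues():
    assert strand_bias_test(10, 10) == pytest.approx(1.0)
    assert strand_bias_test(8, 0) == pytest.approx(2 * 0.5**8)  # closed form 0.0078125
    # brute-force two-sided tail for (60, 20)
    from scipy.stats import binom

    pmf = binom.pmf(np.arange(81), 80, 0.5)
    p_exact = pmf[pmf <= binom.pmf(60, 80, 0.5) * (1 + 1e-9)].sum()
    assert strand_bias_test(60, 20) == pytest.approx(p_exact, rel=1e-9)
    assert strand_bias_test(60, 20) < 1e-5
    assert math.isnan(strand_bias_test(0, 0))


def test_classify_genes_cutoff_and_proportions():
    cl = classify_genes({"g1": 0, "g2": 11, "g3": 3}, cutoff=10)
    assert cl.above_cutoff == ["g2"]
    assert cl.proportion_above == pytest.approx(1 / 3)
    assert cl.proportion_with_any == pytest.approx(2 / 3)
    assert sum(cl.proportions.values()) == pytest.approx(1.0)


def test_classify_genes_all_zero_and_empty():
    cl = classify_genes({"a": 0, "b": 0}, cutoff=5)
    assert cl.above_cutoff == [] and cl.proportion_above == 0.0
    with pytest.raises(ValueError):
        classify_genes({}, cutoff=5)


def test_geneset_counts_totals_and_unknowns():
    counts = pd.DataFrame(
        [
            ("g1", "gene", 3, 2, 1),
            ("g1", "TSS500", 1, 1, 0),
            ("g1", "promoter2000", 2, 1, 1),
            ("g2", "gene", 5, 3, 2),
            ("g2", "TSS500", 0, 0, 0),
            ("g2", "promoter2000", 1, 0, 1),
        ],
        columns=["gene_id", "region_class", "double", "coding", "template"],
    )
    cats = pd.DataFrame(
        [("g1", "PK"), ("g2", "PK"), ("gX", "SS")], columns=["gene_id", "category"]
    )
    per_gene, per_cat, unknown = geneset_counts(cats, counts)
    assert unknown == ["gX"]
    pk = per_cat.set_index("category").loc["PK"]
    assert (pk["gene"], pk["TSS500"], pk["promoter2000"]) == (8, 1, 3)
    # empty category disappears from usable rows rather than erroring
    assert "SS" not in set(per_cat["category"])


def test_chromosome_correlations_perfect_and_degenerate():
    df = pd.DataFrame(
        {
            "g4_density": [0.5, 1.0, 1.5, 2.0],
            "gc_percent": [35.0, 70.0, 105.0, 140.0],  # proportional -> r = 1
            "gene_density": [1.0, 1.0, 1.0, 1.0],      # constant -> flagged
        }
    )
    out = chromosome_correlations(df, features=("gc_percent", "gene_density")).set_index("feature")
    assert out.loc["gc_percent", "pearson_r"] == pytest.approx(1.0)
    assert bool(out.loc["gene_density", "flagged"])
    with pytest.raises(ValueError):
        chromosome_correlations(df.head(2))


def test_correlation_recovers_planted_r_within_fisher_interval():
    rng = np.random.default_rng(11)
    r_target, n = 0.8, 19
    cov = [[1, r_target], [r_target, 1]]
    xy = rng.multivariate_normal([0, 0], cov, size=n)
    df = pd.DataFrame({"g4_density": xy[:, 1] + 5, "gc_percent": xy[:, 0] + 40})
    r_hat = chromosome_correlations(df, features=("gc_percent",))["pearson_r"].iloc[0]
    z = np.arctanh(r_hat)
    half = 1.96 / np.sqrt(n - 3)
    assert np.tanh(z - half) <= r_target <= np.tanh(z + half)


def test_region_densities_recover_planted_coding_bias():
    """A fixture planted only in gene bodies at a 2.45:1 coding:template ratio
    yields a gene-region strand fold of 2.45 up to count quantization."""
    from g4scape import (
        SynthSpec,
        assign_hits,
        derive_regions,
        generate,
        scan_fasta,
        strand_fold,
    )
    from g4scape.stats import region_densities

    spec = SynthSpec(
        seed=17,
        tss_density={"coding": 0.0, "template": 0.0},
        promoter_density={"coding": 0.0, "template": 0.0},
        n_up=0,
        n_down=0,
        n_high_promoter=0,
        n_high_tss=0,
    )
    ds = generate(spec)
    regions = derive_regions(ds.store, ds.contig_lengths)
    hits = []
    from g4scape import detect
    import pandas as pd

    rows = []
    for sid, seq in ds.sequences.items():
        for h in detect(seq, spec.scan, seq_id=sid):
            rows.append((h.seq_id, h.start, h.end, h.strand))
    hits = pd.DataFrame(rows, columns=["seq_id", "start", "end", "strand"])
    dens = region_densities(assign_hits(hits, regions), regions).set_index(
        ["region_class", "context"]
    )
    rec = strand_fold(
        float(dens.loc[("gene", "coding"), "density"]),
        float(dens.loc[("gene", "template"), "density"]),
    )
    assert dens.loc[("gene", "double"), "hit_count"] >= 100
    assert rec.dominant == "coding"
    assert rec.g4sdf == pytest.approx(2.45, rel=0.05)


def test_windowed_track_conserves_counts_and_localizes():
    hits = pd.DataFrame(
        {"seq_id": ["c1"] * 3, "start": [10, 950, 955], "end": [35, 975, 980], "strand": "+"}
    )
    track = windowed_track(hits, {"c1": 2000}, window_bp=500)
    assert track["count"].sum() == 3
    assert track["count"].tolist() == [1, 2, 0, 0]
    empty = windowed_track(hits.iloc[:0], {"c1": 2000}, window_bp=500)
    assert (empty["count"] == 0).all()


def test_windowed_track_variance_shrinks_with_window():
    rng = np.random.default_rng(3)
    starts = np.sort(rng.integers(0, 100_000, size=400))
    hits = pd.DataFrame(
        {"seq_id": "c1", "start": starts, "end": starts + 25, "strand": "+"}
    )
    v_small = windowed_track(hits, {"c1": 100_000}, 1000)["density"].var()
    v_large = windowed_track(hits, {"c1": 100_000}, 10_000)["density"].var()
    assert v_large < v_small


def test_subset_counts_intersects_user_coordinates():
    hits = pd.DataFrame(
        {"seq_id": ["c1", "c1"], "start": [100, 900], "end": [125, 925], "strand": "+"}
    )
    subsets = pd.DataFrame(
        [("cen1", "c1", 0, 500), ("cen2", "c1", 500, 1000)],
        columns=["name", "seq_id", "start", "end"],
    )
    out = subset_counts(hits, subsets)
    assert out["count"].tolist() == [1, 1]
    assert out["density"].tolist() == [density(1, 500)] * 2
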