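"""Window binning, gene annotation, candidate filters, rank-sum integration."""

import numpy as np
import pandas as pd
import pytest

import sweepscan as sw


def make_scan(bins_spec, bin_bp=100_000):
    """Build an iHS-like table: bins_spec = [(n_snps, n_extreme), ...]."""
    rows = []
    for w, (n, k) in enumerate(bins_spec):
        for i in range(n):
            pos = w * bin_bp + 1000 * (i + 1)
            rows.append((pos, 3.0 if i < k else 0.5))
    return pd.DataFrame(rows, columns=["pos", "abs_ihs"])


def test_bin_ihs_toy_counts_and_top_quantile():
    # (25,10) -> 0.40; (30,3) -> 0.10; (19,19) excluded (<20 SNPs)
    scan = make_scan([(25, 10), (30, 3), (19, 19)])
    wins = sw.bin_ihs(scan)
    assert wins.n_snps.tolist() == [25, 30, 19]
    assert wins.n_extreme.tolist() == [10, 3, 19]
    assert wins.included.tolist() == [True, True, False]
    assert wins.fraction[0] == pytest.approx(0.40)
    assert wins.significant.tolist() == [True, False, False]


def test_bin_ihs_no_extreme_scores():
    scan = make_scan([(25, 0), (30, 0)])
    wins = sw.bin_ihs(scan)
    assert (wins.fraction == 0).all()
    # degenerate quantile: all-zero fractions tie at the cutoff and are kept;
    # none carries any evidence (fraction 0), callers filter on fraction > 0
    assert wins.loc[wins.significant, "fraction"].eq(0).all()


def test_bin_ihs_ties_at_cutoff_all_included():
    scan = make_scan([(25, 10), (25, 10), (25, 0)])
    wins = sw.bin_ihs(scan)
    assert wins.significant.tolist() == [True, True, False]


def test_annotate_genes_overlap_and_flank(toys):
    genes, windows = toys["genes"], toys["windows"]
    out = sw.annotate_genes(windows, genes)
    assert out.genes.tolist() == ["g_left,g_span", "g_span,g_mid", "g_right"]
    # boundary: gene starting 100001 bp beyond a peak with flank 100000 is not
    # assigned, but one exactly 100000 bp away is
    near = sw.genes_near_peak(genes, "1", peak_pos=150_000, flank_bp=100_000)
    assert "g_right" not in near.name.tolist()  # g_right starts 100001 bp away
    assert "g_mid" in near.name.tolist()  # peak inside g_mid
    near2 = sw.genes_near_peak(genes, "1", peak_pos=150_001, flank_bp=100_000)
    assert "g_right" in near2.name.tolist()  # exactly 100000 bp away
    far = sw.genes_near_peak(genes, "1", peak_pos=450_002, flank_bp=100_000)
    assert far.empty  # nearest gene end is >100 kb away
    edge = sw.genes_near_peak(genes, "1", peak_pos=410_000, flank_bp=100_000)
    assert "g_out" in edge.name.tolist()  # gene end exactly 100000 bp away


def test_candidate_windows_differential_logic():
    # A has 21 extreme SNPs in window 0; B has none -> retained
    scan_a = make_scan([(30, 21), (30, 21)])
    scan_b = make_scan([(30, 0), (30, 21)])  # window 1 passes in both -> dropped
    out = sw.candidate_windows(scan_a, scan_b, min_extreme=20)
    assert out.start.tolist() == [0]
    # exactly 20 extreme is NOT "> 20"
    scan_a20 = make_scan([(30, 20)])
    assert sw.candidate_windows(scan_a20, scan_b, min_extreme=20).empty


def test_candidate_windows_fixation_filter():
    scan_a = make_scan([(30, 21)])
    scan_b = make_scan([(30, 0)])
    fa = pd.DataFrame({"start": [0], "freq": [1.0]})
    fb = pd.DataFrame({"start": [0], "freq": [0.6]})
    out = sw.candidate_windows(scan_a, scan_b, freq_a=fa, freq_b=fb, fix_thresh=0.95)
    assert len(out) == 1
    fa2 = pd.DataFrame({"start": [0], "freq": [0.9]})
    out2 = sw.candidate_windows(scan_a, scan_b, freq_a=fa2, freq_b=fb, fix_thresh=0.95)
    assert out2.empty


def test_rank_genes_hand_example():
    ev = pd.DataFrame(
        {
            "gene": ["x", "y", "z"],
            "tajima_d_mean": [2.0, 1.0, 0.0],
            "fst_mean": [0.06, 0.05, 0.04],
            "xpehh_max": [4.0, 3.0, 2.0],
        }
    )
    ranked = sw.rank_genes(ev, apply_gates=False)
    assert ranked.gene.tolist() == ["x", "y", "z"]
    assert ranked.rank_score.tolist() == [3.0, 6.0, 9.0]


def test_rank_genes_all_ties_get_average_ranks():
    ev = pd.DataFrame(
        {
            "gene": ["x", "y", "z"],
            "tajima_d_mean": [1.0, 1.0, 1.0],
            "fst_mean": [0.05, 0.05, 0.05],
            "xpehh_max": [3.0, 3.0, 3.0],
        }
    )
    ranked = sw.rank_genes(ev, apply_gates=False)
    assert ranked.rank_score.nunique() == 1
    assert ranked.rank_score.iloc[0] == pytest.approx(6.0)  # rank 2 on each metric


def test_rank_genes_gates():
    ev = pd.DataFrame(
        {
            "gene": list("abcdefghijklmnopqrst"),
            "tajima_d_mean": np.linspace(0, 2, 20),
            "fst_mean": np.linspace(0.01, 0.2, 20),
            "xpehh_max": np.linspace(0, 5, 20),
        }
    )
    ranked = sw.rank_genes(ev, fst_quantile=0.95, xpehh_min=2.5)
    # only genes in the top 5% of F_ST AND xpEHH > 2.5 survive the gates
    assert set(ranked.gene) == {"t"}


def test_intersect_evidence():
    a = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [100]})
    b = pd.DataFrame({"chrom": ["1"], "start": [50], "end": [150]})
    out = sw.intersect_evidence({"x": a, "y": b})
    assert out[["start", "end"]].values.tolist() == [[50, 100]]
    disjoint = pd.DataFrame({"chrom": ["1"], "start": [200], "end": [300]})
    assert sw.intersect_evidence({"x": a, "y": disjoint}).empty
    # three-collection sweep-line check
    c = pd.DataFrame({"chrom": ["1", "1"], "start": [0, 80], "end": [60, 500]})
    out3 = sw.intersect_evidence({"x": a, "y": b, "z": c})
    assert out3[["start", "end"]].values.tolist() == [[50, 60], [80, 100]]
    assert (out3["sources"] == "x,y,z").all()


def test_gene_evidence_aggregation(sweep_panel):
    mats, truth = sweep_panel
    h0, h1 = mats["pop0"], mats["pop1"]
    scan0 = sw.ihs_scan(h0)
    xp = sw.xpehh_scan(h0, h1)
    taj = sw.windowed_tajima_d(h0, 3000)
    fst = sw.wc_fst(
        (np.full(h0.n_sites, h0.n_haplotypes), h0.derived_counts()),
        (np.full(h1.n_sites, h1.n_haplotypes), h1.derived_counts()),
    )
    genes = sw.make_gene_intervals(1_000_000)
    ev = sw.gene_evidence(genes, scan0, taj, fst, h0.positions, xp)
    assert len(ev) == len(genes)
    # frequency column is exactly n_extreme / n_snps where defined
    got = ev.dropna(subset=["freq_extreme"])
    assert np.allclose(got.freq_extreme, got.n_extreme / got.n_snps)
    # the sweep-adjacent genes show elevated F_ST relative to the background
    sweep_genes = ev[(ev.start < truth.sweep_position + 50_000) & (ev.end > truth.sweep_position - 50_000)]
    background = ev[(ev.start > truth.sweep_position + 200_000) | (ev.end < truth.sweep_position - 200_000)]
    assert sweep_genes.fst_mean.max() > background.fst_mean.quantile(0.9)
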