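"""Canned simulation experiments: sweep recovery, F_ST calibration, f3 sign
recovery.

These functions tie the generator to the scan pipeline under the package's
study conditions (two populations of N_e = 500 diploids, 1 Mb of sequence,
50 sampled diploids per population, ~3,100 scan SNPs/Mb) and return the
quantities the method is judged on: whether the sweep-containing 100 kb window
is called significant, whether the top rank-sum gene overlaps it, realized
F_ST at a given split depth, and f3 Z-scores for admixed and unadmixed
targets. Scans run on MAF-prefiltered matrices (the pipeline's filtering
order); the iHS scan keeps border-truncated profiles and xpEHH uses the
pooled-sample shared integration boundary — see the methods note for why
these conventions fit a 1 Mb test genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .f3_admixture import f3_test
from .freq_stats import wc_fst, windowed_tajima_d
from .haplo_stats import ihs_scan, xpehh_scan
from .simgen import SimConfig, SweepSpec, make_gene_intervals, simulate, simulate_frequencies
from .sweep_scan import bin_ihs, gene_evidence, rank_genes
from .types import HaplotypeMatrix

SWEEP_POSITION = 550_000  # mid-window so the footprint is not split across bins
SCAN_MAF = 0.05


def _maf_subset(hm: HaplotypeMatrix, maf: np.ndarray, maf_min: float) -> HaplotypeMatrix:
    return hm.subset_sites(np.flatnonzero(maf >= maf_min))


@dataclass
class SweepRecovery:
    seed: int
    s: float
    sweep_window_significant: bool  # the sweep-containing window is in the top 1%
    significant_within_100kb: bool  # ... or a window adjacent to it is
    top_gene_overlaps_window: bool  # top rank-sum gene overlaps the sweep window
    xpehh_near_sweep: float  # max standardized xpEHH within 100 kb of the sweep
    n_candidate_genes: int
    extreme_fraction_sweep_window: float


def sweep_recovery_replicate(
    seed: int,
    s: float | None = None,
    end_freq: float = 0.75,
    neutral: bool = False,
) -> SweepRecovery | dict:
    """One end-to-end recovery replicate under the study conditions.

    A hard sweep (selection coefficient drawn from U(0.08, 0.1) unless given)
    is planted mid-window in population 0, driven to 75% frequency, and the
    full pipeline is run: per-population MAF filter, iHS scan, 100 kb window
    calling, xpEHH / Tajima's D / F_ST gene evidence, differentiation gates,
    and rank-sum scoring of the genes overlapping significant windows.

    With ``neutral=True`` no sweep is planted and the returned dict reports
    the fraction of included windows called significant (the false-positive
    surface of the top-1% rule).
    """
    rng = np.random.default_rng(seed)
    if s is None:
        s = float(rng.uniform(0.08, 0.1))
    cfg = SimConfig(
        seed=seed,
        sweep=None if neutral else SweepSpec(s=s, position=SWEEP_POSITION, end_freq=end_freq),
    )
    mats, truth = simulate(cfg)
    h0, h1 = mats["pop0"], mats["pop1"]
    f0, f1 = h0.derived_freq(), h1.derived_freq()
    maf0 = np.minimum(f0, 1 - f0)
    fp = (f0 + f1) / 2
    mafp = np.minimum(fp, 1 - fp)

    h0_scan = _maf_subset(h0, maf0, SCAN_MAF)
    scan0 = ihs_scan(h0_scan, discard_border=False)
    windows = bin_ihs(scan0)

    if neutral:
        included = windows["included"]
        return {
            "seed": seed,
            "n_included": int(included.sum()),
            "n_significant": int(windows["significant"].sum()),
            "significant_fraction": float(windows["significant"].sum() / max(included.sum(), 1)),
            "extreme_site_fraction": float((scan0["abs_ihs"] > 2).mean()) if len(scan0) else float("nan"),
        }

    sweep_start = (truth.sweep_position - 1) // 100_000 * 100_000
    w = windows.set_index(windows["start"])
    win_ok = bool(w.loc[sweep_start, "significant"])
    near_ok = bool(
        windows[
            (windows["start"] >= sweep_start - 100_000)
            & (windows["start"] <= sweep_start + 100_000)
        ]["significant"].any()
    )

    h0_xp = _maf_subset(h0, mafp, SCAN_MAF)
    h1_xp = _maf_subset(h1, mafp, SCAN_MAF)
    xp = xpehh_scan(h0_xp, h1_xp, shared_boundary=True)
    taj = windowed_tajima_d(h0, 3000)
    fst = wc_fst(
        (np.full(h0.n_sites, h0.n_haplotypes), h0.derived_counts()),
        (np.full(h1.n_sites, h1.n_haplotypes), h1.derived_counts()),
    )
    genes = make_gene_intervals(cfg.length, gene_bp=20_000, spacing=20_000)
    ev = gene_evidence(genes, scan0, taj, fst, h0.positions, xp)

    # the paper's sequential pipeline: genes come from significant iHS windows,
    # then pass the differentiation gates, then are rank-sum scored
    sig = windows[windows["significant"]]
    in_sig = np.zeros(len(ev), dtype=bool)
    for _, row in sig.iterrows():
        in_sig |= (ev["start"] < row.end) & (ev["end"] > row.start)
    cand = ev[in_sig]
    fst_cut = ev["fst_mean"].quantile(0.95)
    cand = cand[(cand["fst_mean"] >= fst_cut) & (cand["xpehh_max"] > 2.5)]
    ranked = rank_genes(cand, apply_gates=False)
    gene_ok = bool(
        len(ranked)
        and ranked.iloc[0].start < sweep_start + 100_000
        and ranked.iloc[0].end > sweep_start
    )
    near = xp[
        (xp["pos"] > truth.sweep_position - 100_000)
        & (xp["pos"] < truth.sweep_position + 100_000)
    ]
    return SweepRecovery(
        seed=seed,
        s=s,
        sweep_window_significant=win_ok,
        significant_within_100kb=near_ok,
        top_gene_overlaps_window=gene_ok,
        xpehh_near_sweep=float(near["xpehh"].max()) if len(near) else float("nan"),
        n_candidate_genes=int(len(ranked)),
        extreme_fraction_sweep_window=float(w.loc[sweep_start, "fraction"]),
    )


def fst_at_split(seed: int, split_gens: int, length: int = 300_000) -> float:
    """Realized genome-wide Weir-Cockerham F_ST (ratio of sums) between two
    populations separated ``split_gens`` generations at N_e = 500."""
    cfg = SimConfig(seed=seed, length=length, split_gens=split_gens)
    mats, _ = simulate(cfg)
    h0, h1 = mats["pop0"], mats["pop1"]
    rec = wc_fst(
        (np.full(h0.n_sites, h0.n_haplotypes), h0.derived_counts()),
        (np.full(h1.n_sites, h1.n_haplotypes), h1.derived_counts()),
    )
    num = np.nansum(rec["a"])
    den = np.nansum(rec["a"] + rec["b"] + rec["c"])
    return float(num / den)


def f3_replicate(seed: int, alpha: float | None) -> float:
    """Z score of f3(target; A, B) on a 50k-SNP frequency panel where the
    target is an ``alpha``:1-alpha pulse of the sources (or, with
    ``alpha=None``, an unadmixed further-drifted copy of source A)."""
    d = simulate_frequencies(n_snps=50_000, alpha=alpha, seed=seed)
    res = f3_test(d["freq_a"], d["freq_b"], d["freq_c"], d["n_c"], d["positions"])
    return float(res.z)
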