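"""Evidence integration for sweep calling: 100 kb iHS-enrichment windows,
top-quantile significance, gene annotation, differential (selected in A but
not B) candidate filters, interval intersection, and per-gene rank-sum scores.

The windowing rule follows the classic iHS-enrichment scan: tile the genome
in 100 kb bins, compute the fraction of SNPs with |iHS| > 2 per bin, disregard
bins with fewer than 20 SNPs, and call the top 1% of remaining bins
significant (ties at the quantile boundary are all retained). Genes are then
ranked by summing their ranks on Tajima's D mean, F_ST mean and xpEHH max
among genes passing the differentiation gates (F_ST top 5% quantile,
xpEHH > 2.5).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def bin_ihs(
    records: pd.DataFrame,
    bin_bp: int = 100_000,
    ihs_thresh: float = 2.0,
    min_snps: int = 20,
    top_q: float = 0.01,
    chrom: str = "1",
) -> pd.DataFrame:
    """Aggregate an iHS scan into fixed windows and flag the significant ones.

    ``records`` needs ``pos`` (1-based) and ``abs_ihs`` columns (an ``ihs``
    column is folded automatically when ``abs_ihs`` is absent). Windows with
    fewer than ``min_snps`` SNPs are excluded from the quantile and never
    significant. Significant = included windows whose fraction of
    |iHS| > ``ihs_thresh`` SNPs reaches the (1 - top_q) quantile of
    included-window fractions.
    """
    rec = records.copy()
    if "abs_ihs" not in rec.columns:
        rec["abs_ihs"] = rec["ihs"].abs()
    if rec.empty:
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "start": pd.Series(dtype=np.int64),
                "end": pd.Series(dtype=np.int64),
                "n_snps": pd.Series(dtype=np.int64),
                "n_extreme": pd.Series(dtype=np.int64),
                "fraction": pd.Series(dtype=np.float64),
                "included": pd.Series(dtype=bool),
                "significant": pd.Series(dtype=bool),
            }
        )
    pos0 = rec["pos"].to_numpy(np.int64) - 1
    wins = pos0 // bin_bp
    extreme = (rec["abs_ihs"] > ihs_thresh).to_numpy()
    n_windows = int(wins.max()) + 1
    n_snps = np.bincount(wins, minlength=n_windows)
    n_extreme = np.bincount(wins, weights=extreme.astype(float), minlength=n_windows).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(n_snps > 0, n_extreme / np.maximum(n_snps, 1), np.nan)
    included = n_snps >= min_snps

    significant = np.zeros(n_windows, dtype=bool)
    if included.any():
        cut = np.quantile(fraction[included], 1 - top_q)
        significant = included & (fraction >= cut)

    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_windows) * bin_bp,
            "end": (np.arange(n_windows) + 1) * bin_bp,
            "n_snps": n_snps,
            "n_extreme": n_extreme,
            "fraction": fraction,
            "included": included,
            "significant": significant,
        }
    )


def annotate_genes(
    windows: pd.DataFrame,
    genes: pd.DataFrame,
    flank_bp: int = 0,
) -> pd.DataFrame:
    """Attach the list of overlapping gene names to each window.

    Overlap is on 0-based half-open coordinates, with the window optionally
    extended by ``flank_bp`` on each side (the convention for "genes within
    100 kb of a peak"). Returns the windows frame with a ``genes`` column
    (comma-joined names, "" when none).
    """
    out = windows.copy()
    gene_lists = []
    for _, w in windows.iterrows():
        lo = w.start - flank_bp
        hi = w.end + flank_bp
        m = (genes["chrom"] == w.chrom) & (genes["start"] < hi) & (genes["end"] > lo)
        gene_lists.append(",".join(genes.loc[m, "name"].tolist()))
    out["genes"] = gene_lists
    return out


def genes_near_peak(
    genes: pd.DataFrame, chrom: str, peak_pos: int, flank_bp: int = 100_000
) -> pd.DataFrame:
    """Genes whose interval lies within ``flank_bp`` of a peak site (1-based)."""
    p0 = peak_pos - 1
    m = (
        (genes["chrom"] == chrom)
        & (genes["start"] < p0 + flank_bp + 1)
        & (genes["end"] > p0 - flank_bp)
    )
    return genes.loc[m].reset_index(drop=True)


def candidate_windows(
    scan_a: pd.DataFrame,
    scan_b: pd.DataFrame,
    bin_bp: int = 100_000,
    ihs_thresh: float = 2.0,
    min_extreme: int = 20,
    freq_a: pd.DataFrame | None = None,
    freq_b: pd.DataFrame | None = None,
    fix_thresh: float | None = None,
    chrom: str = "1",
) -> pd.DataFrame:
    """Differential candidate windows: selected in population A but not B.

    Step 1: windows where population A has more than ``min_extreme`` SNPs with
    |iHS| > ``ihs_thresh``. Step 2: drop windows that also pass in population
    B. Step 3 (optional, needs per-window selected-allele frequencies): keep
    only windows whose top allele frequency is >= ``fix_thresh`` in A and
    < ``fix_thresh`` in B.

    ``freq_a``/``freq_b`` are frames with ``start`` and ``freq`` columns keyed
    by window start.
    """

    def passing(scan: pd.DataFrame) -> pd.DataFrame:
        rec = scan.copy()
        if "abs_ihs" not in rec.columns:
            rec["abs_ihs"] = rec["ihs"].abs()
        pos0 = rec["pos"].to_numpy(np.int64) - 1
        wins = pos0 // bin_bp
        extreme = (rec["abs_ihs"] > ihs_thresh).to_numpy()
        counts: dict[int, int] = {}
        for w, e in zip(wins, extreme):
            if e:
                counts[int(w)] = counts.get(int(w), 0) + 1
        return {w for w, cnt in counts.items() if cnt > min_extreme}

    pass_a = passing(scan_a)
    pass_b = passing(scan_b)
    kept = sorted(pass_a - pass_b)

    rows = []
    for w in kept:
        row = {"chrom": chrom, "start": w * bin_bp, "end": (w + 1) * bin_bp}
        if fix_thresh is not None and freq_a is not None and freq_b is not None:
            fa = freq_a.loc[freq_a["start"] == w * bin_bp, "freq"]
            fb = freq_b.loc[freq_b["start"] == w * bin_bp, "freq"]
            if fa.empty or fb.empty:
                continue
            if not (float(fa.iloc[0]) >= fix_thresh and float(fb.iloc[0]) < fix_thresh):
                continue
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def gene_evidence(
    genes: pd.DataFrame,
    ihs: pd.DataFrame,
    tajima: pd.DataFrame,
    fst_records: pd.DataFrame,
    fst_positions: np.ndarray,
    xpehh: pd.DataFrame,
    ihs_thresh: float = 2.0,
) -> pd.DataFrame:
    """Per-gene evidence table: |iHS| max/mean, extreme-SNP fraction, Tajima's D
    mean (over overlapping windows), F_ST mean (ratio-of-sums over SNPs in the
    gene), and xpEHH max.

    Gene intervals are 0-based half-open; site positions 1-based. Genes with
    no iHS SNPs get NaN iHS columns but are retained.
    """
    ihs_pos0 = ihs["pos"].to_numpy(np.int64) - 1 if len(ihs) else np.array([], dtype=np.int64)
    xp_pos0 = xpehh["pos"].to_numpy(np.int64) - 1 if len(xpehh) else np.array([], dtype=np.int64)
    fst_pos0 = np.asarray(fst_positions, dtype=np.int64) - 1

    rows = []
    for _, g in genes.iterrows():
        m_ihs = (ihs_pos0 >= g.start) & (ihs_pos0 < g.end)
        sub = ihs.loc[m_ihs]
        n_tot = int(m_ihs.sum())
        if n_tot:
            abs_i = sub["abs_ihs"] if "abs_ihs" in sub else sub["ihs"].abs()
            n_ext = int((abs_i > ihs_thresh).sum())
            ihs_max = float(abs_i.max())
            ihs_mean = float(abs_i.mean())
            freq_ext = n_ext / n_tot
        else:
            n_ext, ihs_max, ihs_mean, freq_ext = 0, float("nan"), float("nan"), float("nan")

        m_taj = (tajima["start"] < g.end) & (tajima["end"] > g.start) & tajima["D"].notna()
        taj_mean = float(tajima.loc[m_taj, "D"].mean()) if m_taj.any() else float("nan")

        m_fst = (fst_pos0 >= g.start) & (fst_pos0 < g.end)
        sub_f = fst_records.loc[m_fst]
        ok = sub_f["a"].notna()
        if ok.any():
            den = (sub_f.loc[ok, "a"] + sub_f.loc[ok, "b"] + sub_f.loc[ok, "c"]).sum()
            fst_mean = float(sub_f.loc[ok, "a"].sum() / den) if den != 0 else float("nan")
        else:
            fst_mean = float("nan")

        m_xp = (xp_pos0 >= g.start) & (xp_pos0 < g.end)
        xp_max = float(xpehh.loc[m_xp, "xpehh"].max()) if m_xp.any() else float("nan")

        rows.append(
            (
                g.chrom, g.start, g.end, g.get("name", "."),
                ihs_max, ihs_mean, freq_ext, n_ext, n_tot, taj_mean, fst_mean, xp_max,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "gene",
            "ihs_max", "ihs_mean", "freq_extreme", "n_extreme", "n_snps",
            "tajima_d_mean", "fst_mean", "xpehh_max",
        ],
    )


def rank_genes(
    evidence: pd.DataFrame,
    fst_quantile: float = 0.95,
    xpehh_min: float = 2.5,
    apply_gates: bool = True,
) -> pd.DataFrame:
    """Rank genes by summed ranks on Tajima's D mean, F_ST mean and xpEHH max.

    With ``apply_gates`` the candidate set is first restricted to genes above
    the ``fst_quantile`` quantile of F_ST mean and with xpEHH max >
    ``xpehh_min``. Each metric is ranked best-first (larger = rank 1; ties get
    the average rank); the rank score is the sum of the three ranks and the
    output is sorted ascending by it.
    """
    ev = evidence.copy()
    if apply_gates and len(ev):
        fst_cut = ev["fst_mean"].quantile(fst_quantile)
        ev = ev[(ev["fst_mean"] >= fst_cut) & (ev["xpehh_max"] > xpehh_min)]
    ev = ev.copy()
    if len(ev) == 0:
        ev["rank_score"] = pd.Series(dtype=np.float64)
        return ev
    for col in ("tajima_d_mean", "fst_mean", "xpehh_max"):
        ev[f"rank_{col}"] = ev[col].rank(ascending=False, method="average", na_option="bottom")
    ev["rank_score"] = (
        ev["rank_tajima_d_mean"] + ev["rank_fst_mean"] + ev["rank_xpehh_max"]
    )
    return ev.sort_values("rank_score", kind="stable").reset_index(drop=True)


def intersect_evidence(sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Intersect named interval collections (0-based half-open, sorted).

    Returns the intervals present in every collection, annotated with the
    contributing set names. Empty input or any empty collection gives an
    empty result.
    """
    names = list(sets)
    if not names or any(len(sets[n]) == 0 for n in names):
        return pd.DataFrame(columns=["chrom", "start", "end", "sources"])

    def to_list(df: pd.DataFrame) -> list[tuple[str, int, int]]:
        return [(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]

    current = to_list(sets[names[0]])
    for name in names[1:]:
        other = to_list(sets[name])
        merged = []
        for c1, s1, e1 in current:
            for c2, s2, e2 in other:
                if c1 == c2 and s1 < e2 and s2 < e1:
                    merged.append((c1, max(s1, s2), min(e1, e2)))
        current = sorted(set(merged))
        if not current:
            break
    return pd.DataFrame(
        [(c, s, e, ",".join(names)) for c, s, e in current],
        columns=["chrom", "start", "end", "sources"],
    )
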