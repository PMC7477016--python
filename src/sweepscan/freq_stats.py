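"""Allele-frequency statistics: inbreeding F, windowed Tajima's D, and the
Weir–Cockerham F_ST estimator.

Tajima's D is computed in fixed-width windows (3 kb by default) from phased
haplotypes; F_ST is the two-population variance-components estimator, with
region means taken as ratio-of-sums over the per-site components (the low-bias
convention). Undefined values are reported as NaN, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, HaplotypeMatrix


def inbreeding_f(gm: GenotypeMatrix, freqs: np.ndarray | None = None) -> np.ndarray:
    """Per-individual inbreeding coefficient from observed vs expected homozygosity.

    F = (O_hom - E_hom) / (L_called - E_hom), where E_hom sums, over the
    individual's called polymorphic sites, 1 - 2p(1-p) * 2n/(2n-1) with p the
    alt-allele frequency and n the number of called genotypes at the site
    (the small-sample correction of the method-of-moments estimator).

    Sites with p in {0, 1} carry no information and are excluded. Individuals
    with zero called polymorphic sites get NaN.
    """
    d = gm.dosages
    called = d != MISSING
    n_called = called.sum(axis=0)
    if freqs is None:
        alt = np.where(called, d, 0).sum(axis=0)
        total = 2 * n_called
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    p = np.asarray(freqs, dtype=np.float64)
    poly = (p > 0) & (p < 1) & (n_called > 0)
    two_n = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        e_het_site = 2 * p * (1 - p) * (two_n / np.maximum(two_n - 1, 1))
    e_hom_site = np.where(poly, 1.0 - e_het_site, 0.0)

    use = called & poly  # per-individual, per-site contribution mask
    o_hom = ((d != 1) & use).sum(axis=1).astype(np.float64)
    e_hom = use @ e_hom_site
    l_called = use.sum(axis=1).astype(np.float64)
    denom = l_called - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where((l_called > 0) & (denom != 0), (o_hom - e_hom) / denom, np.nan)
    return f


def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajima_d(n: int, S: int, pi: float) -> float:
    """Tajima's D from haplotype count n, segregating sites S and mean pairwise
    diversity pi. Returns NaN when S = 0 (undefined, not zero)."""
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 haplotypes")
    if S < 0 or pi < 0:
        raise ValueError("S and pi must be non-negative")
    if S == 0:
        return float("nan")
    k = _tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi - S / k["a1"]) / np.sqrt(var))


@dataclass
class TajimaWindow:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    n_snps: int
    S: int
    pi: float
    D: float


def windowed_tajima_d(hm: HaplotypeMatrix, window_bp: int = 3000) -> pd.DataFrame:
    """Tajima's D in non-overlapping windows tiling each chromosome.

    pi is the mean number of pairwise differences between haplotypes within
    the window, computed per site as 2*c*(n-c)/(n*(n-1)) summed over window
    columns. Windows with S = 0 are emitted with D = NaN.
    """
    n = hm.n_haplotypes
    counts = hm.derived_counts()
    poly = (counts > 0) & (counts < n)
    pi_site = 2.0 * counts * (n - counts) / (n * (n - 1))

    chroms = hm.chrom if hm.chrom is not None else np.repeat("1", hm.n_sites)
    rows = []
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        pos0 = hm.positions[m] - 1  # 0-based
        cpoly = poly[m]
        cpi = pi_site[m]
        last = int(pos0.max()) if len(pos0) else -1
        n_windows = last // window_bp + 1 if last >= 0 else 0
        wins = pos0 // window_bp
        for w in range(n_windows):
            sel = wins == w
            S = int(cpoly[sel].sum())
            pi = float(cpi[sel].sum())
            D = tajima_d(n, S, pi) if (S > 0 and n >= 4) else float("nan")
            rows.append(
                (str(chrom), w * window_bp, (w + 1) * window_bp, int(sel.sum()), S, pi, D)
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "S", "pi", "D"])


def wc_fst(
    counts_pop1: tuple[np.ndarray, np.ndarray],
    counts_pop2: tuple[np.ndarray, np.ndarray],
) -> pd.DataFrame:
    """Per-site Weir–Cockerham variance components from haploid allele counts.

    Parameters are ``(n, alt_count)`` pairs per population, where ``n`` is the
    number of called chromosomes. Returns a frame with components ``a``
    (between-population) and ``b`` (within-population; the haploid-data form
    has no separate within-individual term, reported as ``c = 0``) and
    ``fst = a/(a+b+c)``. Sites monomorphic across both populations, or with
    n < 2 in either, get NaN.
    """
    n1, x1 = (np.asarray(v, dtype=np.float64) for v in counts_pop1)
    n2, x2 = (np.asarray(v, dtype=np.float64) for v in counts_pop2)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = x1 / n1
        p2 = x2 / n2
        n_bar = (n1 + n2) / r
        n_c = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r
        )
    c = np.zeros_like(a)
    denom = a + b + c
    undefined = (n1 < 2) | (n2 < 2) | ((p1 % 1 == 0) & (p1 == p2)) | ~np.isfinite(denom)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(~undefined & (denom != 0), a / denom, np.nan)
    a = np.where(undefined, np.nan, a)
    b = np.where(undefined, np.nan, b)
    return pd.DataFrame({"a": a, "b": b, "c": c, "fst": fst})


def wc_fst_from_genotypes(
    gm1: GenotypeMatrix, gm2: GenotypeMatrix
) -> pd.DataFrame:
    """Convenience wrapper: per-site WC components from two genotype matrices."""

    def counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
        called = gm.dosages != MISSING
        n = 2 * called.sum(axis=0)
        alt = np.where(called, gm.dosages, 0).sum(axis=0)
        return n, alt

    return wc_fst(counts(gm1), counts(gm2))


def region_mean_fst(
    records: pd.DataFrame,
    positions: np.ndarray,
    intervals: pd.DataFrame,
    chroms: np.ndarray | None = None,
    method: str = "ratio_of_sums",
) -> pd.DataFrame:
    """Mean F_ST per interval.

    ``ratio_of_sums`` (default) pools the variance components: sum(a)/sum(a+b+c).
    ``mean_of_ratios`` averages per-site fst instead. Intervals are 0-based
    half-open; ``positions`` are 1-based site coordinates. Empty intervals get
    NaN.
    """
    if method not in ("ratio_of_sums", "mean_of_ratios"):
        raise ValueError(f"unknown method: {method}")
    pos0 = np.asarray(positions) - 1
    rows = []
    for _, iv in intervals.iterrows():
        m = (pos0 >= iv.start) & (pos0 < iv.end)
        if chroms is not None:
            m &= chroms == iv.chrom
        sub = records.loc[m]
        ok = sub["a"].notna()
        if not ok.any():
            val = float("nan")
        elif method == "ratio_of_sums":
            num = sub.loc[ok, "a"].sum()
            den = (sub.loc[ok, "a"] + sub.loc[ok, "b"] + sub.loc[ok, "c"]).sum()
            val = float(num / den) if den != 0 else float("nan")
        else:
            val = float(sub.loc[ok, "fst"].mean())
        rows.append((iv.chrom, iv.start, iv.end, iv.get("name", "."), int(ok.sum()), val))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "n_snps", "fst"]
    )
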