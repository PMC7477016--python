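"""Three-population admixture test f3(Target; A, B) with block-jackknife
standard errors.

The per-SNP statistic is (c - a)(c - b) - h_c / n_c, where a, b, c are the
allele frequencies in the two sources and the target, and h_c / n_c is the
finite-sample correction for the target's heterozygosity
(h_c = c(1-c) * n_c/(n_c - 1); n_c = called chromosomes in the target).
A significantly negative mean over SNPs indicates the target derives from a
mixture of populations related to the two sources. Standard errors come from
a delete-one-block weighted jackknife over contiguous genomic blocks, which
is robust to linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class F3Result:
    target: str
    source_a: str
    source_b: str
    f3: float
    se: float
    z: float
    n_snps: int
    n_blocks: int
    block_span: int


def f3_per_snp(
    freq_a: np.ndarray,
    freq_b: np.ndarray,
    freq_c: np.ndarray,
    n_c: np.ndarray | int,
    correction: bool = True,
) -> np.ndarray:
    """Per-SNP f3 contribution (c-a)(c-b), bias-corrected for the target's
    finite sample size when ``correction`` is on."""
    a = np.asarray(freq_a, dtype=np.float64)
    b = np.asarray(freq_b, dtype=np.float64)
    c = np.asarray(freq_c, dtype=np.float64)
    for name, v in (("freq_a", a), ("freq_b", b), ("freq_c", c)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} outside [0,1]")
    val = (c - a) * (c - b)
    if correction:
        n = np.asarray(n_c, dtype=np.float64)
        if np.any(n < 2):
            raise ValueError("target sample must have at least 2 chromosomes")
        h_c = c * (1 - c) * n / (n - 1)
        val = val - h_c / n
    return val


def _assign_blocks(chroms: np.ndarray, positions: np.ndarray, block_span: int) -> np.ndarray:
    """Contiguous-run block ids: SNPs fall into ``block_span``-bp slabs per
    chromosome; ids are globally unique and ordered."""
    block = np.zeros(len(positions), dtype=np.int64)
    next_id = 0
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        slabs = (positions[m] - 1) // block_span
        _, local = np.unique(slabs, return_inverse=True)
        block[m] = local + next_id
        next_id = block[m].max() + 1
    return block


def f3_test(
    freq_a: np.ndarray,
    freq_b: np.ndarray,
    freq_c: np.ndarray,
    n_c: np.ndarray | int,
    positions: np.ndarray,
    chroms: np.ndarray | None = None,
    block_span: int = 5_000_000,
    labels: tuple[str, str, str] = ("C", "A", "B"),
) -> F3Result:
    """f3(Target; A, B) over a SNP panel with a weighted block jackknife.

    SNPs with an undefined frequency in any population are dropped listwise.
    The estimate is the mean per-SNP contribution; the SE is the weighted
    delete-one-block jackknife (block weights = SNP counts). Z = f3 / SE;
    negative Z is evidence that the target is admixed between the sources.
    """
    a = np.asarray(freq_a, dtype=np.float64)
    b = np.asarray(freq_b, dtype=np.float64)
    c = np.asarray(freq_c, dtype=np.float64)
    n = np.broadcast_to(np.asarray(n_c, dtype=np.float64), a.shape)
    positions = np.asarray(positions, dtype=np.int64)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (n >= 2)
    a, b, c, n, positions = a[ok], b[ok], c[ok], n[ok], positions[ok]
    chrom_arr = (
        np.asarray(chroms)[ok] if chroms is not None else np.repeat("1", len(positions))
    )
    if len(a) == 0:
        raise ValueError("no usable SNPs for f3")

    contrib = f3_per_snp(a, b, c, n)
    block = _assign_blocks(chrom_arr, positions, block_span)
    block_ids = np.unique(block)
    g = len(block_ids)
    if g < 2:
        raise ValueError("f3 jackknife requires at least 2 non-empty blocks")

    total = contrib.sum()
    n_snps = len(contrib)
    estimate = total / n_snps

    block_sums = np.array([contrib[block == bid].sum() for bid in block_ids])
    block_n = np.array([(block == bid).sum() for bid in block_ids], dtype=np.float64)
    # delete-one estimates and weighted jackknife (Busing et al. 1999)
    theta_del = (total - block_sums) / (n_snps - block_n)
    h = n_snps / block_n  # inverse block weights
    theta_jack = g * estimate - ((1 - block_n / n_snps) * theta_del).sum()
    tau = h * estimate - (h - 1) * theta_del  # pseudo-values
    var = np.mean((tau - theta_jack) ** 2 / (h - 1))
    se = float(np.sqrt(var))

    z = estimate / se if se > 0 else float("nan")
    return F3Result(
        target=labels[0],
        source_a=labels[1],
        source_b=labels[2],
        f3=float(estimate),
        se=se,
        z=float(z),
        n_snps=n_snps,
        n_blocks=g,
        block_span=block_span,
    )


def f3_all_pairs(
    freqs: dict[str, np.ndarray],
    n_chrom: dict[str, np.ndarray | int],
    target: str,
    positions: np.ndarray,
    chroms: np.ndarray | None = None,
    block_span: int = 5_000_000,
) -> pd.DataFrame:
    """Run f3(target; A, B) for every unordered source pair, as the survey
    design does. Returns one row per pair, sorted by Z."""
    sources = [p for p in freqs if p != target]
    rows = []
    for i, pa in enumerate(sources):
        for pb in sources[i + 1 :]:
            res = f3_test(
                freqs[pa],
                freqs[pb],
                freqs[target],
                n_chrom[target],
                positions,
                chroms,
                block_span,
                labels=(target, pa, pb),
            )
            rows.append(
                (res.target, res.source_a, res.source_b, res.f3, res.se, res.z, res.n_snps, res.n_blocks)
            )
    df = pd.DataFrame(
        rows, columns=["target", "source_a", "source_b", "f3", "se", "z", "n_snps", "n_blocks"]
    )
    return df.sort_values("z").reset_index(drop=True)
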