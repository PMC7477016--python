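"""Variant and sample QC: the filtering cascade applied before any analysis.

Site filters run in a fixed order — missingness, minor-allele count, minor
allele frequency, Hardy–Weinberg exact test — followed by an individual
missingness filter and then a stage-specific step: LD thinning (population
structure analyses) or a stricter MAF floor (selection scans). Each step
reports exactly how many sites it removed, so the cascade is auditable:
removed + surviving = input at every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import MISSING, GenotypeMatrix, SiteTable


@dataclass
class FilterConfig:
    """Thresholds for the QC cascade.

    Defaults follow the standard stringency for mixed-depth cohort data:
    sites with >10% missing calls, minor allele count < 3, MAF < 1% or a
    Hardy–Weinberg exact p < 0.001 are removed, then individuals with >10%
    missing data; population-structure analyses additionally thin to pairwise
    r^2 < 0.1 and selection scans drop MAF < 5%.
    """

    max_site_missing: float = 0.10
    min_minor_allele_count: int = 3
    min_maf: float = 0.01
    hwe_p_min: float = 0.001
    max_indiv_missing: float = 0.10
    ld_r2_max: float = 0.1
    scan_maf_min: float = 0.05
    ld_window_snps: int = 50
    ld_step_snps: int = 5

    def __post_init__(self) -> None:
        for name in (
            "max_site_missing",
            "min_maf",
            "hwe_p_min",
            "max_indiv_missing",
            "ld_r2_max",
            "scan_maf_min",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class FilterReport:
    """Per-step removal counts plus surviving dimensions."""

    steps: list[tuple[str, int]] = field(default_factory=list)
    removed_individuals: list[str] = field(default_factory=list)
    n_sites_in: int = 0
    n_sites_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    metadata: dict = field(default_factory=dict)

    def add(self, step: str, n_removed: int) -> None:
        self.steps.append((step, int(n_removed)))

    def total_removed(self) -> int:
        return sum(n for _, n in self.steps)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy–Weinberg test (Wigginton et al. convention).

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all configurations no more likely
    than the observed one. Returns a p-value in (0, 1].
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare-allele copies
    # P(het = h | allele counts) ∝ 2^h * n! / (hom_r! h! hom_c!) — compute in logs
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    lg = math.lgamma
    logp = np.array(
        [
            h * math.log(2.0) + lg(n + 1) - lg(hr + 1) - lg(h + 1) - lg(hc + 1)
            for h, hr, hc in zip(hets, hom_rare, hom_common)
        ]
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def site_stats(gm: GenotypeMatrix) -> dict[str, np.ndarray]:
    """Per-site call rate, minor allele frequency/count, and HWE exact p.

    Sites with zero called genotypes get ``maf = nan`` and ``hwe_p = nan``.
    """
    d = gm.dosages
    called = d != MISSING
    n_called = called.sum(axis=0)
    d0 = np.where(called, d, 0)
    alt = d0.sum(axis=0)
    total = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    maf = np.where(total > 0, np.minimum(p_alt, 1 - p_alt), np.nan)
    mac = np.where(total > 0, np.minimum(alt, total - alt), 0).astype(np.int64)
    call_rate = n_called / gm.n_samples

    n_het = ((d == 1) & called).sum(axis=0)
    n_hom_alt = ((d == 2) & called).sum(axis=0)
    n_hom_ref = n_called - n_het - n_hom_alt
    hwe_p = np.full(gm.n_sites, np.nan)
    for j in range(gm.n_sites):
        if n_called[j] > 0:
            hwe_p[j] = hwe_exact_test(int(n_hom_ref[j]), int(n_het[j]), int(n_hom_alt[j]))
    return {"call_rate": call_rate, "maf": maf, "mac": mac, "hwe_p": hwe_p}


def ld_prune(
    gm: GenotypeMatrix,
    r2_max: float = 0.1,
    window_snps: int = 50,
    step_snps: int = 5,
) -> np.ndarray:
    """Greedy LD thinning: indices of sites kept so every retained pair within
    a sliding window has squared dosage correlation < ``r2_max``.

    Sites are visited in position order; on conflict the earlier site wins.
    Missing genotypes are mean-imputed only inside the correlation computation.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    d = gm.dosages.astype(np.float64)
    d[gm.dosages == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    filled = np.where(np.isnan(d), col_mean, d)
    centered = filled - filled.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))

    L = gm.n_sites
    keep = np.ones(L, dtype=bool)
    start = 0
    while start < L:
        end = min(start + window_snps, L)
        idx = [j for j in range(start, end) if keep[j]]
        for a_i, j in enumerate(idx):
            if not keep[j]:
                continue
            for k in idx[a_i + 1 :]:
                if not keep[k]:
                    continue
                if norms[j] == 0 or norms[k] == 0:
                    continue  # monomorphic after imputation: r2 undefined
                r = centered[:, j] @ centered[:, k] / (norms[j] * norms[k])
                if r * r >= r2_max:
                    keep[k] = False
        if end == L:
            break
        start += step_snps
    return np.flatnonzero(keep)


def apply_filter_cascade(
    gm: GenotypeMatrix,
    st: SiteTable,
    cfg: FilterConfig | None = None,
    stage: str = "population",
) -> tuple[GenotypeMatrix, SiteTable, FilterReport]:
    """Run the full QC cascade and return filtered matrices plus a report.

    Order: site missingness → minor allele count → MAF → HWE → individual
    missingness → stage step (``population``: LD thinning; ``scan``: MAF ≥
    scan_maf_min). The report records removals per step; the minor-allele-count
    step treats "fewer than 3 copies of the minor allele" as the removal rule.
    """
    if cfg is None:
        cfg = FilterConfig()
    if stage not in ("population", "scan"):
        raise ValueError(f"unknown stage: {stage}")

    report = FilterReport(
        n_sites_in=gm.n_sites,
        n_samples_in=gm.n_samples,
        metadata={"stage": stage, "mac_rule": "minor allele count < min_minor_allele_count"},
    )
    cur_gm, cur_st = gm, st

    def drop_sites(mask_keep: np.ndarray, label: str) -> None:
        nonlocal cur_gm, cur_st
        n_removed = int((~mask_keep).sum())
        report.add(label, n_removed)
        if n_removed:
            idx = np.flatnonzero(mask_keep)
            cur_gm = cur_gm.subset(site_idx=idx)
            cur_st = cur_st.subset(idx)

    stats = site_stats(cur_gm)
    drop_sites(
        (1 - stats["call_rate"]) <= cfg.max_site_missing, "site_missingness"
    )
    stats = site_stats(cur_gm)
    drop_sites(stats["mac"] >= cfg.min_minor_allele_count, "minor_allele_count")
    stats = site_stats(cur_gm)
    with np.errstate(invalid="ignore"):
        drop_sites(~(stats["maf"] < cfg.min_maf), "maf")
    stats = site_stats(cur_gm)
    with np.errstate(invalid="ignore"):
        drop_sites(~(stats["hwe_p"] < cfg.hwe_p_min), "hwe")

    # individual missingness
    miss = (cur_gm.dosages == MISSING).mean(axis=1) if cur_gm.n_sites else np.zeros(
        cur_gm.n_samples
    )
    keep_ind = miss <= cfg.max_indiv_missing
    report.removed_individuals = [
        s for s, k in zip(cur_gm.samples, keep_ind) if not k
    ]
    report.add("individual_missingness", int((~keep_ind).sum()))
    if not keep_ind.all():
        cur_gm = cur_gm.subset(sample_idx=np.flatnonzero(keep_ind))

    if stage == "population":
        if cur_gm.n_sites:
            kept = ld_prune(cur_gm, cfg.ld_r2_max, cfg.ld_window_snps, cfg.ld_step_snps)
            mask = np.zeros(cur_gm.n_sites, dtype=bool)
            mask[kept] = True
        else:
            mask = np.ones(0, dtype=bool)
        drop_sites(mask, "ld_thinning")
    else:
        stats = site_stats(cur_gm)
        with np.errstate(invalid="ignore"):
            drop_sites(~(stats["maf"] < cfg.scan_maf_min), "scan_maf")

    report.n_sites_out = cur_gm.n_sites
    report.n_samples_out = cur_gm.n_samples
    return cur_gm, cur_st, report
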