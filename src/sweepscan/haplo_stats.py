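"""Haplotype-based selection statistics: EHH decay, iHH integration,
standardized iHS, and cross-population xpEHH.

EHH at a distance x from a core site is the probability that two randomly
chosen chromosomes carrying the core allele are identical over the stretch
core→x: sum_h C(m_h, 2) / C(n, 2) over the distinct extended haplotypes h.
iHH integrates EHH against physical position (trapezoid rule), each direction
truncated where EHH first falls below a cutoff (linearly interpolating the
crossing). iHS is ln(iHH_ancestral / iHH_derived) standardized within
derived-allele-frequency bins; xpEHH is the genome-wide-standardized
ln(iHH_pop1 / iHH_pop2) from allele-agnostic profiles. Extreme standardized
values mark the long, unbroken haplotypes that recent hard sweeps leave.

Distances are physical (bp); no genetic map is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import HaplotypeMatrix

try:  # numba accelerates the per-site arm extension ~20x; pure-python fallback
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000


@dataclass
class EhhProfile:
    """One-sided EHH decay curves around a core site.

    ``positions``/``ehh`` run outward from the core (the core itself is the
    first entry with ehh = 1.0). ``defined`` is False when fewer than two
    chromosomes carry the core allele.
    """

    core_index: int
    core_pos: int
    allele: str  # "ancestral" | "derived" | "all"
    n_core: int
    left_pos: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    left_ehh: np.ndarray = field(default_factory=lambda: np.array([]))
    right_pos: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    right_ehh: np.ndarray = field(default_factory=lambda: np.array([]))
    defined: bool = True
    # arm ended at the chromosome end or a gap while EHH was still above the
    # extension threshold (candidate for border discarding during integration)
    left_truncated: bool = False
    right_truncated: bool = False


def _ehh_side(
    haps: np.ndarray,
    carriers: np.ndarray,
    positions: np.ndarray,
    core: int,
    step: int,
    include_core_column: bool,
    stop_below: float,
    max_gap: int | None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Extend outward from the core in one direction (step = +1 or -1).

    Returns (positions, ehh, truncated) starting at the core (ehh = 1.0).
    Group identity is refined site by site via counting-sort relabelling;
    extension stops when EHH = 0, when it falls below ``stop_below`` (the
    integration cutoff — values past the first crossing cannot contribute),
    at a gap larger than ``max_gap``, or at the chromosome end. ``truncated``
    is True when the arm ended at the chromosome end or a gap with EHH still
    at or above ``stop_below``.
    """
    gap = -1 if max_gap is None else int(max_gap)
    pos, vals, m, ended_inside = _ehh_arm_kernel(
        haps,
        np.asarray(carriers, dtype=np.int64),
        np.asarray(positions, dtype=np.int64),
        core,
        step,
        include_core_column,
        stop_below,
        gap,
    )
    truncated = (not ended_inside) and vals[m - 1] >= stop_below
    return pos[:m].copy(), vals[:m].copy(), truncated


@njit(cache=True)
def _ehh_arm_kernel(
    haps, carriers, positions, core, step, include_core, stop_below, max_gap
):  # pragma: no cover - exercised via _ehh_side
    n = carriers.shape[0]
    pairs_total = n * (n - 1) / 2.0
    L = haps.shape[1]
    out_pos = np.empty(L + 1, np.int64)
    out_ehh = np.empty(L + 1, np.float64)
    ids = np.zeros(n, np.int64)
    n_groups = 1
    if include_core:
        mx = 0
        for i in range(n):
            ids[i] = haps[carriers[i], core]
            if ids[i] > mx:
                mx = ids[i]
        n_groups = mx + 1
    out_pos[0] = positions[core]
    out_ehh[0] = 1.0
    m = 1
    j = core + step
    prev = positions[core]
    ended_inside = False
    counts = np.zeros(2 * n + 2, np.int64)
    comb = np.empty(n, np.int64)
    relabel = np.empty(2 * n + 2, np.int64)
    while 0 <= j < L:
        d = positions[j] - prev
        if d < 0:
            d = -d
        if max_gap > 0 and d > max_gap:
            break
        hi = 2 * n_groups
        for i in range(hi):
            counts[i] = 0
        for i in range(n):
            c = ids[i] * 2 + haps[carriers[i], j]
            comb[i] = c
            counts[c] += 1
        s = 0
        for i in range(hi):
            s += counts[i] * (counts[i] - 1)
        e = s / 2.0 / pairs_total
        out_pos[m] = positions[j]
        out_ehh[m] = e
        m += 1
        if e == 0.0 or e < stop_below:
            ended_inside = True
            break
        g = 0
        for i in range(hi):
            if counts[i] > 0:
                relabel[i] = g
                g += 1
        for i in range(n):
            ids[i] = relabel[comb[i]]
        n_groups = g
        prev = positions[j]
        j += step
    return out_pos, out_ehh, m, ended_inside


def ehh(
    hm: HaplotypeMatrix,
    core: int,
    allele: str = "derived",
    stop_below: float = 0.0,
    max_gap: int | None = DEFAULT_MAX_GAP,
) -> EhhProfile:
    """EHH decay profile around a core site, both directions.

    ``allele`` selects the chromosomes the profile conditions on:
    ``"ancestral"`` (allele 0), ``"derived"`` (allele 1) or ``"all"`` (every
    chromosome, the site-EHH used by xpEHH). In every case the profile starts
    at 1.0 at the core and decays with haplotype identity AROUND the core:
    the core allele itself does not partition the chromosomes, so the
    allele-agnostic profile is insensitive to core-site heterozygosity (the
    site-EHH normalization convention). With fewer than two carriers the
    profile is undefined.
    """
    if allele not in ("ancestral", "derived", "all"):
        raise ValueError(f"unknown allele selector: {allele}")
    col = hm.haplotypes[:, core]
    if allele == "all":
        carriers = np.arange(hm.n_haplotypes)
    else:
        carriers = np.flatnonzero(col == (1 if allele == "derived" else 0))
    prof = EhhProfile(
        core_index=core,
        core_pos=int(hm.positions[core]),
        allele=allele,
        n_core=len(carriers),
    )
    if len(carriers) < 2:
        prof.defined = False
        return prof
    include_core = False
    prof.left_pos, prof.left_ehh, prof.left_truncated = _ehh_side(
        hm.haplotypes, carriers, hm.positions, core, -1, include_core, stop_below, max_gap
    )
    prof.right_pos, prof.right_ehh, prof.right_truncated = _ehh_side(
        hm.haplotypes, carriers, hm.positions, core, +1, include_core, stop_below, max_gap
    )
    return prof


def _ihh_side(pos: np.ndarray, ehh_vals: np.ndarray, cutoff: float) -> float:
    """Trapezoidal integral of one EHH arm, truncated at the first crossing
    below ``cutoff`` (linear interpolation of the crossing point)."""
    if len(pos) < 2:
        return 0.0
    x = np.abs(pos.astype(np.float64) - float(pos[0]))
    total = 0.0
    for i in range(1, len(x)):
        e0, e1 = ehh_vals[i - 1], ehh_vals[i]
        if e1 >= cutoff:
            total += 0.5 * (e0 + e1) * (x[i] - x[i - 1])
        else:
            if e0 > cutoff:  # interpolate where ehh crosses the cutoff
                frac = (e0 - cutoff) / (e0 - e1)
                total += 0.5 * (e0 + cutoff) * frac * (x[i] - x[i - 1])
            break
    return total


def ihh(
    profile: EhhProfile, cutoff: float = DEFAULT_CUTOFF, discard_border: bool = False
) -> float:
    """Integrated EHH (bp · homozygosity): both arms of a profile, each
    truncated at its own cutoff crossing. NaN when the profile is undefined,
    or — with ``discard_border`` — when either arm reached the chromosome end
    (or a gap) before EHH decayed below the cutoff, the scan convention that
    avoids spuriously variable scores near chromosome borders."""
    if not profile.defined:
        return float("nan")
    if discard_border:
        left_hit = profile.left_truncated and (
            len(profile.left_ehh) == 0 or profile.left_ehh[-1] >= cutoff
        )
        right_hit = profile.right_truncated and (
            len(profile.right_ehh) == 0 or profile.right_ehh[-1] >= cutoff
        )
        if left_hit or right_hit:
            return float("nan")
    return _ihh_side(profile.left_pos, profile.left_ehh, cutoff) + _ihh_side(
        profile.right_pos, profile.right_ehh, cutoff
    )


def ihs_scan(
    hm: HaplotypeMatrix,
    maf_min: float = 0.05,
    freq_bin_width: float = 0.05,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int | None = DEFAULT_MAX_GAP,
    discard_border: bool = True,
) -> pd.DataFrame:
    """Genome scan of standardized iHS.

    For every site with minor allele frequency >= ``maf_min``, integrates the
    ancestral- and derived-allele EHH profiles and forms the unstandardized
    score ln(iHH_A / iHH_D). Scores are standardized to mean 0, sd 1 within
    derived-frequency bins of width ``freq_bin_width``; bins with fewer than
    two sites fall back to pooled moments (flagged). Sites with an undefined or
    zero iHH on either allele are excluded (``n_excluded`` in ``df.attrs``);
    with ``discard_border`` (default) this includes sites whose EHH is still
    above the cutoff at the chromosome end or at a gap.

    Returns a frame with site index, position, derived frequency, iHH pair,
    raw and standardized scores, and |iHS|.
    """
    n = hm.n_haplotypes
    freq = hm.derived_freq()
    maf = np.minimum(freq, 1 - freq)
    scan_idx = np.flatnonzero(maf >= maf_min)

    rows = []
    n_excluded = 0
    for j in scan_idx:
        ihh_vals = {}
        for allele in ("ancestral", "derived"):
            prof = ehh(hm, int(j), allele, stop_below=cutoff, max_gap=max_gap)
            ihh_vals[allele] = ihh(prof, cutoff, discard_border=discard_border)
        ia, id_ = ihh_vals["ancestral"], ihh_vals["derived"]
        if not (np.isfinite(ia) and np.isfinite(id_)) or ia <= 0 or id_ <= 0:
            n_excluded += 1
            continue
        rows.append((int(j), int(hm.positions[j]), float(freq[j]), ia, id_, np.log(ia / id_)))

    df = pd.DataFrame(
        rows, columns=["site", "pos", "freq", "ihh_a", "ihh_d", "raw"]
    )
    df.attrs["n_excluded"] = n_excluded
    df.attrs["n_haplotypes"] = n
    if df.empty:
        df["bin"] = pd.Series(dtype=np.int64)
        df["ihs"] = pd.Series(dtype=np.float64)
        df["abs_ihs"] = pd.Series(dtype=np.float64)
        df["pooled_moments"] = pd.Series(dtype=bool)
        return df
    df["bin"] = np.minimum(
        (df["freq"] / freq_bin_width).astype(int),
        int(np.ceil(1.0 / freq_bin_width)) - 1,
    )
    df["ihs"] = standardize_by_bin(df["raw"].to_numpy(), df["bin"].to_numpy(), df)
    df["abs_ihs"] = df["ihs"].abs()
    return df


def standardize_by_bin(
    raw: np.ndarray, bins: np.ndarray, df: pd.DataFrame | None = None
) -> np.ndarray:
    """Z-standardize values within bins; bins with < 2 members (or zero
    variance) use pooled moments instead. Marks ``pooled_moments`` on ``df``
    when given."""
    out = np.empty_like(raw, dtype=np.float64)
    pooled_mean = raw.mean()
    pooled_sd = raw.std(ddof=0)
    flagged = np.zeros(len(raw), dtype=bool)
    for b in np.unique(bins):
        m = bins == b
        if m.sum() >= 2 and raw[m].std(ddof=0) > 0:
            out[m] = (raw[m] - raw[m].mean()) / raw[m].std(ddof=0)
        else:
            sd = pooled_sd if pooled_sd > 0 else 1.0
            out[m] = (raw[m] - pooled_mean) / sd
            flagged[m] = True
    if df is not None:
        df["pooled_moments"] = flagged
    return out


def xpehh_scan(
    hm1: HaplotypeMatrix,
    hm2: HaplotypeMatrix,
    maf_min: float = 0.05,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int | None = DEFAULT_MAX_GAP,
    shared_boundary: bool = False,
    discard_border: bool = True,
) -> pd.DataFrame:
    """Cross-population xpEHH scan over the shared site set.

    Per site, the allele-agnostic EHH profile is integrated within each
    population and the unstandardized score is ln(iHH_pop1 / iHH_pop2),
    standardized genome-wide. Positive extremes mean longer haplotypes
    (candidate selection) in population 1. ``maf_min`` applies to the pooled
    minor allele frequency. With ``shared_boundary`` both integrals stop at
    the boundary where the EHH of the pooled two-population sample decays
    below the cutoff (the original cross-population convention) instead of
    each at its own crossing.
    """
    if hm1.n_sites != hm2.n_sites or not np.array_equal(hm1.positions, hm2.positions):
        raise ValueError("xpEHH requires identical site sets in both populations")
    c1 = hm1.derived_counts()
    c2 = hm2.derived_counts()
    n_tot = hm1.n_haplotypes + hm2.n_haplotypes
    freq = (c1 + c2) / n_tot
    maf = np.minimum(freq, 1 - freq)
    scan_idx = np.flatnonzero(maf >= maf_min)

    pooled = None
    if shared_boundary:
        pooled = HaplotypeMatrix(
            np.concatenate([hm1.haplotypes, hm2.haplotypes], axis=0),
            hm1.positions,
            list(hm1.samples) + list(hm2.samples),
            hm1.chrom,
        )
    rows = []
    n_excluded = 0
    stop = 0.0 if shared_boundary else cutoff
    for j in scan_idx:
        p1 = ehh(hm1, int(j), "all", stop_below=stop, max_gap=max_gap)
        p2 = ehh(hm2, int(j), "all", stop_below=stop, max_gap=max_gap)
        if shared_boundary:
            pp = ehh(pooled, int(j), "all", stop_below=cutoff, max_gap=max_gap)
            i1, i2 = _shared_boundary_ihh(p1, p2, pp, cutoff)
        else:
            i1 = ihh(p1, cutoff, discard_border=discard_border)
            i2 = ihh(p2, cutoff, discard_border=discard_border)
        if not (np.isfinite(i1) and np.isfinite(i2)) or i1 <= 0 or i2 <= 0:
            n_excluded += 1
            continue
        rows.append((int(j), int(hm1.positions[j]), float(freq[j]), i1, i2, np.log(i1 / i2)))

    df = pd.DataFrame(rows, columns=["site", "pos", "freq", "ihh1", "ihh2", "raw"])
    df.attrs["n_excluded"] = n_excluded
    if df.empty:
        df["xpehh"] = pd.Series(dtype=np.float64)
        return df
    sd = df["raw"].std(ddof=0)
    df["xpehh"] = (df["raw"] - df["raw"].mean()) / (sd if sd > 0 else 1.0)
    return df


def _truncate_arm(pos: np.ndarray, vals: np.ndarray, limit: float) -> float:
    """Integrate one arm out to ``limit`` bp from the core (no cutoff)."""
    if len(pos) < 2:
        return 0.0
    x = np.abs(pos.astype(np.float64) - float(pos[0]))
    total = 0.0
    for i in range(1, len(x)):
        if x[i] <= limit:
            total += 0.5 * (vals[i - 1] + vals[i]) * (x[i] - x[i - 1])
        else:
            if x[i - 1] < limit:
                frac = (limit - x[i - 1]) / (x[i] - x[i - 1])
                e_at = vals[i - 1] + frac * (vals[i] - vals[i - 1])
                total += 0.5 * (vals[i - 1] + e_at) * (limit - x[i - 1])
            break
    return total


def _crossing_distance(pos: np.ndarray, vals: np.ndarray, cutoff: float) -> float:
    """Distance from the core at which EHH first crosses below ``cutoff``
    (interpolated); +inf if it never does within the profile."""
    if len(pos) < 2:
        return 0.0
    x = np.abs(pos.astype(np.float64) - float(pos[0]))
    for i in range(1, len(x)):
        if vals[i] < cutoff:
            if vals[i - 1] > cutoff:
                frac = (vals[i - 1] - cutoff) / (vals[i - 1] - vals[i])
                return x[i - 1] + frac * (x[i] - x[i - 1])
            return x[i - 1]
    return float("inf")


def _shared_boundary_ihh(
    p1: EhhProfile, p2: EhhProfile, pooled: EhhProfile, cutoff: float
) -> tuple[float, float]:
    """iHH pair with both populations integrated on each side out to the
    boundary where the pooled-sample EHH crosses the cutoff."""
    if not (p1.defined and p2.defined and pooled.defined):
        return float("nan"), float("nan")
    out = [0.0, 0.0]
    for pos1, v1, pos2, v2, posp, vp in (
        (p1.left_pos, p1.left_ehh, p2.left_pos, p2.left_ehh, pooled.left_pos, pooled.left_ehh),
        (p1.right_pos, p1.right_ehh, p2.right_pos, p2.right_ehh, pooled.right_pos, pooled.right_ehh),
    ):
        lim = _crossing_distance(posp, vp, cutoff)
        if not np.isfinite(lim):
            lim = abs(float(posp[-1]) - float(posp[0])) if len(posp) else 0.0
        out[0] += _truncate_arm(pos1, v1, lim)
        out[1] += _truncate_arm(pos2, v2, lim)
    return out[0], out[1]
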