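"""EHH/iHH/iHS/xpEHH vs brute-force oracles and their analytic limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import sweepscan as sw
from sweepscan.haplo_stats import ehh, ihh, ihs_scan, xpehh_scan

from conftest import random_haplotype_matrix


# -- brute-force oracles -------------------------------------------------------------


def ehh_bruteforce(haps, positions, core, carriers, include_core):
    """EHH by direct distinct-haplotype counting with tuple grouping."""
    n = len(carriers)
    pairs = n * (n - 1) / 2
    out = {}
    for direction in (-1, +1):
        vals = [(positions[core], 1.0)]
        j = core + direction
        while 0 <= j < haps.shape[1]:
            lo, hi = min(core, j), max(core, j)
            span = slice(lo, hi + 1)
            groups = {}
            for h in carriers:
                key = tuple(haps[h, span]) if include_core else tuple(
                    np.delete(haps[h, span], core - lo)
                )
                groups[key] = groups.get(key, 0) + 1
            e = sum(c * (c - 1) / 2 for c in groups.values()) / pairs
            vals.append((positions[j], e))
            if e == 0:
                break
            j += direction
        out[direction] = vals
    return out


def ihh_numeric_oracle(pos, vals, cutoff):
    """Trapezoid integral on a dense grid with the crossing found numerically."""
    if len(pos) < 2:
        return 0.0
    x = np.abs(np.asarray(pos, float) - pos[0])
    y = np.asarray(vals, float)
    end = x[-1]
    below = np.flatnonzero(y < cutoff)
    if len(below):
        i = below[0]
        if y[i - 1] > cutoff:
            end = x[i - 1] + (y[i - 1] - cutoff) / (y[i - 1] - y[i]) * (x[i] - x[i - 1])
        else:
            end = x[i - 1]
    grid = np.unique(np.concatenate([np.linspace(0, end, 20001), x[x <= end], [end]]))
    return float(np.trapezoid(np.interp(grid, x, y), grid))


# -- EHH -----------------------------------------------------------------------------


def test_ehh_at_core_is_one_and_identical_haplotypes_stay_one():
    haps = np.tile(np.array([0, 1, 0, 1], dtype=np.uint8), (4, 1))
    hm = sw.HaplotypeMatrix(haps, np.array([10, 20, 30, 40]), ["a", "b"])
    prof = ehh(hm, 1, "derived")
    assert prof.right_ehh[0] == 1.0
    assert np.all(prof.right_ehh == 1.0) and np.all(prof.left_ehh == 1.0)


def test_ehh_hand_example_two_distinct_extensions(toys):
    # haplotypes {00, 01} carry allele 0 at site 0; at site 1 they split -> EHH 0
    hm = toys["ehh"]
    sub = hm.haplotypes[:2]
    hm2 = sw.HaplotypeMatrix(sub, hm.positions, ["e0"])
    prof = ehh(hm2, 0, "ancestral")
    assert prof.n_core == 2
    assert prof.right_ehh[-1] == 0.0


def test_ehh_undefined_with_single_carrier():
    haps = np.array([[1, 0], [0, 0], [0, 1], [0, 0]], dtype=np.uint8)
    hm = sw.HaplotypeMatrix(haps, np.array([10, 20]), ["a", "b"])
    assert not ehh(hm, 0, "derived").defined


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None)
def test_ehh_matches_bruteforce_and_is_monotone(seed):
    """Random instances up to 32 haplotypes x 64 sites agree with the
    tuple-grouping oracle and decay monotonically from the core."""
    rng = np.random.default_rng(seed)
    n_hap = int(rng.integers(2, 17)) * 2
    n_sites = int(rng.integers(4, 65))
    hm = random_haplotype_matrix(rng, n_hap, n_sites)
    core = int(rng.integers(0, n_sites))
    for allele, include_core in (("derived", False), ("ancestral", False), ("all", False)):
        prof = ehh(hm, core, allele, max_gap=None)
        if not prof.defined:
            continue
        col = hm.haplotypes[:, core]
        carriers = (
            np.arange(n_hap)
            if allele == "all"
            else np.flatnonzero(col == (1 if allele == "derived" else 0))
        )
        oracle = ehh_bruteforce(hm.haplotypes, hm.positions, core, carriers, include_core)
        for direction, (o_pos, o_vals) in (
            (-1, (prof.left_pos, prof.left_ehh)),
            (+1, (prof.right_pos, prof.right_ehh)),
        ):
            expect = oracle[direction][: len(o_pos)]
            assert [p for p, _ in expect] == list(o_pos)
            assert np.allclose([v for _, v in expect], o_vals, atol=1e-9)
            assert np.all(np.diff(o_vals) <= 1e-12)  # monotone non-increasing


# -- iHH -----------------------------------------------------------------------------


def test_ihh_trapezoid_examples():
    prof = sw.EhhProfile(
        core_index=0,
        core_pos=0,
        allele="derived",
        n_core=4,
        left_pos=np.array([0]),
        left_ehh=np.array([1.0]),
        right_pos=np.array([0, 1000]),
        right_ehh=np.array([1.0, 0.5]),
    )
    assert ihh(prof, cutoff=0.0) == pytest.approx(750.0)
    # flat profile over 10 kb on both sides
    pos = np.arange(0, 10_001, 1000)
    flat = sw.EhhProfile(
        core_index=0,
        core_pos=0,
        allele="derived",
        n_core=4,
        left_pos=pos,
        left_ehh=np.ones(len(pos)),
        right_pos=pos,
        right_ehh=np.ones(len(pos)),
    )
    assert ihh(flat, cutoff=0.05) == pytest.approx(20_000.0)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None)
def test_ihh_matches_numeric_integration_oracle(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, 30))
    pos = np.concatenate([[0], np.sort(rng.choice(np.arange(1, 50_000), m, replace=False))])
    vals = np.concatenate([[1.0], np.sort(rng.uniform(0, 1, m))[::-1]])
    prof = sw.EhhProfile(
        core_index=0,
        core_pos=0,
        allele="derived",
        n_core=4,
        left_pos=np.array([0]),
        left_ehh=np.array([1.0]),
        right_pos=pos,
        right_ehh=vals,
    )
    assert ihh(prof, cutoff=0.05) == pytest.approx(
        ihh_numeric_oracle(pos, vals, 0.05), abs=1e-6
    )


def test_ihh_border_discard():
    prof = sw.EhhProfile(
        core_index=0,
        core_pos=0,
        allele="derived",
        n_core=4,
        left_pos=np.array([0]),
        left_ehh=np.array([1.0]),
        right_pos=np.array([0, 1000]),
        right_ehh=np.array([1.0, 0.5]),
        left_truncated=True,  # chromosome end reached while EHH still 1.0
        right_truncated=True,
    )
    assert np.isnan(ihh(prof, cutoff=0.05, discard_border=True))
    assert np.isfinite(ihh(prof, cutoff=0.05, discard_border=False))


# -- iHS -----------------------------------------------------------------------------


def test_ihs_standardization_binwise_exact(sweep_panel):
    hm = sweep_panel[0]["pop1"]  # the neutral sister population, 1 Mb panel
    df = ihs_scan(hm)
    assert len(df) > 100
    n_checked = 0
    for b, sub in df.groupby("bin"):
        if len(sub) >= 2 and not sub["pooled_moments"].any():
            assert sub["ihs"].mean() == pytest.approx(0.0, abs=1e-9)
            assert sub["ihs"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
            n_checked += 1
    assert n_checked > 5


def test_ihs_raw_is_log_ratio_of_ihh(sweep_panel):
    hm = sweep_panel[0]["pop1"]
    df = ihs_scan(hm)
    assert len(df) > 0
    assert np.allclose(df["raw"], np.log(df["ihh_a"] / df["ihh_d"]))


# -- xpEHH ---------------------------------------------------------------------------


def test_xpehh_identical_populations_raw_zero(small_neutral_panel):
    hm, _ = small_neutral_panel
    df = xpehh_scan(hm, hm)
    assert len(df) > 0
    assert np.allclose(df["raw"], 0.0)


def test_xpehh_antisymmetric_under_population_swap(two_pop_panel):
    mats, _ = two_pop_panel
    d12 = xpehh_scan(mats["pop0"], mats["pop1"])
    d21 = xpehh_scan(mats["pop1"], mats["pop0"])
    merged = d12.merge(d21, on="site", suffixes=("_12", "_21"))
    assert len(merged) > 0
    assert np.allclose(merged["raw_12"], -merged["raw_21"], atol=1e-12)


def test_xpehh_shared_boundary_convention_runs(two_pop_panel):
    mats, _ = two_pop_panel
    d = xpehh_scan(mats["pop0"], mats["pop1"], shared_boundary=True)
    assert len(d) > 0
    assert np.isfinite(d["xpehh"]).all()
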