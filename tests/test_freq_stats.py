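"""Frequency statistics vs independent formula oracles and analytic limits."""

import numpy as np
import pandas as pd
import pytest

import sweepscan as sw
from sweepscan.freq_stats import _tajima_constants
from sweepscan.types import GenotypeMatrix


# -- independent oracles -------------------------------------------------------------


def tajima_d_oracle(n, S, pi):
    """Constant-by-constant reimplementation (kept deliberately separate)."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / (e1 * S + e2 * S * (S - 1)) ** 0.5


def wc_fst_oracle(n1, x1, n2, x2):
    """Two-population haploid-count variance components, coded independently."""
    p1, p2 = x1 / n1, x2 / n2
    nbar = (n1 + n2) / 2
    nc = n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)  # r - 1 = 1
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2)
    return a, b


# -- inbreeding F --------------------------------------------------------------------


def test_inbreeding_f_fully_homozygous_is_one():
    # all individuals homozygous at sites with p = 0.5 -> F = 1 for everyone
    d = np.array([[0, 2, 0, 2], [2, 0, 2, 0]], dtype=np.int8)
    f = sw.inbreeding_f(GenotypeMatrix(["a", "b"], d))
    assert np.allclose(f, 1.0)


def test_inbreeding_f_zero_at_expected_heterozygosity():
    # with known p = 0.5 and 2n -> the correction factor, engineer O_hom = E_hom
    # using explicit freqs so expectation is analytic: E_het = 2*0.5*0.5*(2n/(2n-1))
    n = 5
    d = np.zeros((n, 8), dtype=np.int8)
    # individual 0: heterozygous at a fraction matching expectation is impossible
    # exactly with integer counts unless E_het per site * L is an integer; use
    # freqs supplied externally so e_het = 0.5 per site -> E_hom = 4 of 8 sites
    freqs = np.full(8, 0.5)
    two_n = 2 * n
    e_het = 2 * 0.5 * 0.5 * (two_n / (two_n - 1))
    # choose het count k so numerator (8-k) - (8 - 8*e_het) = 0 => k = 8*e_het
    # 8*e_het = 8*5/9... not integer; instead verify formula directly against a
    # hand computation for an arbitrary pattern
    d[0] = [1, 1, 0, 2, 1, 0, 2, 1]
    f = sw.inbreeding_f(GenotypeMatrix([f"s{i}" for i in range(n)], d), freqs=freqs)
    o_hom = 4
    e_hom = 8 * (1 - e_het)
    assert f[0] == pytest.approx((o_hom - e_hom) / (8 - e_hom))


def test_inbreeding_f_random_mating_near_zero():
    # needs a site-rich panel: the F estimate per individual averages over sites
    cfg = sw.SimConfig(
        n_e=200, length=1_000_000, n_pops=1, split_gens=0, n_samples=50,
        burn_in_gens=100, seed=21,
    )
    mats, _ = sw.simulate(cfg)
    hm = mats["pop0"]
    gm = GenotypeMatrix(hm.samples, hm.to_dosages())
    f = sw.inbreeding_f(gm)
    assert abs(np.nanmean(f)) < 0.03  # random pairing: no inbreeding signal


# -- Tajima's D ----------------------------------------------------------------------


def test_tajima_d_zero_identity_and_sign():
    a1 = _tajima_constants(10)["a1"]
    S = 16
    assert sw.tajima_d(10, S, S / a1) == pytest.approx(0.0, abs=1e-12)
    assert sw.tajima_d(10, S, S / a1 + 1) > 0
    assert sw.tajima_d(10, S, S / a1 - 1) < 0
    assert np.isnan(sw.tajima_d(10, 0, 0.0))  # undefined, not zero


@pytest.mark.parametrize("n,S,pi", [(10, 16, 3.1), (4, 1, 0.5), (40, 120, 33.3), (25, 7, 2.0)])
def test_tajima_d_matches_oracle(n, S, pi):
    assert sw.tajima_d(n, S, pi) == pytest.approx(tajima_d_oracle(n, S, pi), abs=1e-12)


def test_windowed_tajima_singleton_window():
    # one singleton among 10 haplotypes: S=1, pi = 2*1*9/(10*9) = 0.2
    haps = np.zeros((10, 1), dtype=np.uint8)
    haps[0, 0] = 1
    hm = sw.HaplotypeMatrix(haps, np.array([500]), [f"s{i}" for i in range(5)])
    w = sw.windowed_tajima_d(hm, window_bp=3000)
    assert len(w) == 1
    assert w.S[0] == 1
    assert w.pi[0] == pytest.approx(0.2)
    assert w.n_snps[0] == 1


def test_windowed_tajima_duplicate_haplotypes_negative_branch():
    # column counts 0 or n -> no polymorphism in-window after dedup; make two
    # identical haplotype groups: pi=0 at a polymorphic site is impossible, so
    # use a window whose only variation is shared -> actually test pi=0 window
    haps = np.tile(np.array([[0], [0]], dtype=np.uint8), (5, 1))
    hm = sw.HaplotypeMatrix(haps, np.array([100]), [f"s{i}" for i in range(5)])
    w = sw.windowed_tajima_d(hm, window_bp=3000)
    assert w.S[0] == 0 and np.isnan(w.D[0])


def test_windowed_tajima_partition_invariance(small_neutral_panel):
    hm, _ = small_neutral_panel
    w = sw.windowed_tajima_d(hm, window_bp=3000)
    # splitting the chromosome at a window boundary changes nothing
    cut_bp = 30_000
    left = hm.subset_sites(np.flatnonzero(hm.positions <= cut_bp))
    right = hm.subset_sites(np.flatnonzero(hm.positions > cut_bp))
    w_left = sw.windowed_tajima_d(left, window_bp=3000)
    joined = pd.concat([w_left, sw.windowed_tajima_d(right, window_bp=3000)])
    merged = joined.groupby("start", as_index=False).agg(
        {"S": "sum", "pi": "sum", "n_snps": "sum"}
    )
    orig = w[w.n_snps > 0].reset_index(drop=True)
    m = merged[merged.n_snps > 0].reset_index(drop=True)
    assert np.array_equal(orig.S.to_numpy(), m.S.to_numpy())
    assert np.allclose(orig.pi.to_numpy(), m.pi.to_numpy())


# -- Weir-Cockerham F_ST -------------------------------------------------------------


def test_fst_fixed_difference_is_one():
    rec = sw.wc_fst((np.array([100]), np.array([100])), (np.array([100]), np.array([0])))
    assert rec.fst[0] == pytest.approx(1.0)


def test_fst_matches_oracle_on_random_counts():
    rng = np.random.default_rng(5)
    n1 = rng.integers(4, 60, size=50)
    n2 = rng.integers(4, 60, size=50)
    x1 = rng.integers(1, n1)
    x2 = rng.integers(1, n2)
    rec = sw.wc_fst((n1, x1), (n2, x2))
    for j in range(50):
        a, b = wc_fst_oracle(n1[j], x1[j], n2[j], x2[j])
        assert rec.a[j] == pytest.approx(a, abs=1e-12)
        assert rec.b[j] == pytest.approx(b, abs=1e-12)
        if a + b != 0:
            assert rec.fst[j] == pytest.approx(a / (a + b), abs=1e-12)


def test_fst_panmictic_mean_near_zero():
    # two samples drawn from one panmictic pool
    rng = np.random.default_rng(8)
    p = rng.uniform(0.05, 0.95, size=2000)
    x1 = rng.binomial(50, p)
    x2 = rng.binomial(50, p)
    rec = sw.wc_fst((np.full(2000, 50), x1), (np.full(2000, 50), x2))
    mean = np.nansum(rec.a) / np.nansum(rec.a + rec.b + rec.c)
    assert abs(mean) < 0.01  # small negatives allowed


def test_fst_monomorphic_both_is_undefined():
    rec = sw.wc_fst((np.array([40]), np.array([0])), (np.array([40]), np.array([0])))
    assert np.isnan(rec.fst[0])


def test_region_mean_fst_ratio_of_sums():
    rec = pd.DataFrame({"a": [1.0, 0.0], "b": [1.0, 1.0], "c": [0.0, 0.0], "fst": [0.5, 0.0]})
    pos = np.array([150, 250])
    iv = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [1000], "name": ["r"]})
    out = sw.region_mean_fst(rec, pos, iv)
    assert out.fst[0] == pytest.approx(1 / 3)  # (1+0)/(2+1)
    single = sw.region_mean_fst(rec.iloc[:1], pos[:1], iv)
    assert single.fst[0] == pytest.approx(0.5)  # single site = per-site value
    # order invariance
    out2 = sw.region_mean_fst(rec.iloc[::-1].reset_index(drop=True), pos[::-1], iv)
    assert out2.fst[0] == pytest.approx(out.fst[0])
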