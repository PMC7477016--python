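"""Shared fixtures: toy matrices and (session-scoped) simulated panels."""

import numpy as np
import pytest

import sweepscan as sw


@pytest.fixture(scope="session")
def toys():
    return sw.make_toy_fixtures()


@pytest.fixture(scope="session")
def small_neutral_panel():
    """A small single-population neutral panel (fast; reused across tests)."""
    cfg = sw.SimConfig(
        n_e=100, length=200_000, n_pops=1, split_gens=0, n_samples=20, seed=42
    )
    mats, truth = sw.simulate(cfg)
    return mats["pop0"], truth


@pytest.fixture(scope="session")
def two_pop_panel():
    """A small neutral two-population panel with shared site set."""
    cfg = sw.SimConfig(
        n_e=100, length=200_000, n_pops=2, split_gens=10, n_samples=20, seed=43
    )
    mats, truth = sw.simulate(cfg)
    return mats, truth


@pytest.fixture(scope="session")
def sweep_panel():
    """One two-population panel with a completed hard sweep in pop0."""
    cfg = sw.SimConfig(
        seed=7, sweep=sw.SweepSpec(s=0.08, position=550_000, end_freq=0.95)
    )
    mats, truth = sw.simulate(cfg)
    return mats, truth


def random_haplotype_matrix(rng, n_hap=16, n_sites=24, length=100_000):
    """Random phased matrix for oracle comparisons (columns kept polymorphic)."""
    haps = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.uint8)
    # re-draw monomorphic columns so every site is usable
    for j in range(n_sites):
        while haps[:, j].min() == haps[:, j].max():
            haps[:, j] = rng.integers(0, 2, size=n_hap)
    positions = np.sort(rng.choice(np.arange(1, length), size=n_sites, replace=False))
    samples = [f"s{i}" for i in range(n_hap // 2)]
    return sw.HaplotypeMatrix(haps, positions, samples, np.repeat("1", n_sites))
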