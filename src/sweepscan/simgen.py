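"""Forward Wright–Fisher simulator producing phased cohort-like panels.

The generator emulates the statistical structure of a two-population
whole-genome cohort: neutral background variation at mutation–drift
equilibrium, between-population drift after a clean split, an optional pulse
of admixture, and an optional hard selective sweep confined to one
population. It exists so that every pipeline stage is testable without
restricted-access genomes.

Model: discrete generations, N_e diploids per population, multinomial
resampling weighted by fitness (1, 1+s/2, 1+s additive at the sweep site in
the selected population only), Poisson mutation onto fresh sites
(infinite-sites; position collisions re-drawn, no back mutation), and
single-crossover recombination with probability r*L per meiosis at a uniform
breakpoint. Populations split by copying; an admixture pulse builds each
target haplotype from source A with probability alpha. Diploid samples are
formed by random haplotype pairing at output time and written as a phased
VCF 4.2 with the AA (ancestral allele) tag. Everything is deterministic
under the seed.

To keep multi-replicate experiments desk-scale, the founding population is
drawn from the stationary neutral site-frequency spectrum (E[# sites at
derived count i] = theta/i) with random carrier assignment, then evolved
N_e further generations so linkage disequilibrium builds up before any
split or sweep; see the methods note for what this does and does not
equilibrate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, HaplotypeMatrix, PopulationMap, SiteTable
from .vcf_io import write_vcf


@dataclass
class SweepSpec:
    """A hard sweep: additive fitness 1 : 1+s/2 : 1+s in one population."""

    population: int = 0
    position: int | None = None  # default: middle of the sequence
    s: float = 0.08
    start_freq: float = 0.05
    end_freq: float = 0.95
    max_restarts: int = 50


@dataclass
class AdmixtureSpec:
    """Pulse admixture: a target population founded from two sources."""

    source_a: int = 0
    source_b: int = 1
    alpha: float = 0.5
    gens_after: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0,1]")


@dataclass
class SimConfig:
    """Study-condition defaults: two populations of N_e = 500 diploids, a 1 Mb
    region, 50 sampled diploids per population (the cohort's per-population
    scale), and rescaled per-generation rates giving a few thousand
    segregating sites in the sample."""

    n_e: int = 500
    length: int = 1_000_000
    mu: float = 5.5e-7  # per bp per gen (rescaled); ~3,100 MAF>=5% sites per Mb sampled
    r: float = 2.5e-7  # per bp per gen (rescaled); see methods note on calibration
    n_pops: int = 2
    split_gens: int = 22  # drift depth; ~F_ST 0.011-0.025 regime at N_e=500
    burn_in_gens: int | None = None  # default: N_e
    n_samples: int = 50  # diploids sampled per population
    sweep: SweepSpec | None = None
    admix: AdmixtureSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 0 or self.r < 0:
            raise ValueError("rates must be non-negative")
        if self.sweep is not None and self.sweep.population >= max(self.n_pops, 1):
            raise ValueError("sweep population must exist")
        if 2 * self.n_samples > 2 * self.n_e:
            raise ValueError("cannot sample more haplotypes than the population holds")


@dataclass
class TruthRecord:
    """Ground truth written alongside every simulated panel."""

    seed: int
    n_pops: int
    split_gens_nominal: int
    split_gens_realized: int
    sweep_position: int | None = None
    sweep_s: float | None = None
    sweep_population: int | None = None
    sweep_freq: dict = field(default_factory=dict)  # pop label -> realized frequency
    sweep_restarts: int = 0
    alpha: float | None = None
    n_sites_out: int = 0


class SweepLostError(RuntimeError):
    """The sweep allele was lost more times than the retry cap allows."""


class _Population:
    """Mutable haplotype pool: 2N rows, columns shared across populations."""

    def __init__(self, haps: np.ndarray):
        self.haps = haps  # uint8, 2N x S

    @property
    def n_dip(self) -> int:
        return self.haps.shape[0] // 2

    def copy(self) -> "_Population":
        return _Population(self.haps.copy())


def _stationary_init(
    rng: np.random.Generator, n_hap: int, theta: float, length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a founding panel from the stationary neutral SFS.

    The expected number of sites at derived count i (1 <= i < n_hap) is
    theta/i; carriers are assigned uniformly at random (no initial LD).
    Returns (haplotypes, positions); positions are distinct uniform integers.
    """
    counts = []
    for i in range(1, n_hap):
        k = rng.poisson(theta / i)
        counts.extend([i] * k)
    counts = np.array(counts, dtype=np.int64)
    rng.shuffle(counts)
    S = len(counts)
    haps = np.zeros((n_hap, S), dtype=np.uint8)
    for j, c in enumerate(counts):
        haps[rng.choice(n_hap, size=c, replace=False), j] = 1
    positions = _fresh_positions(rng, S, length, set())
    return haps, positions


def _fresh_positions(
    rng: np.random.Generator, k: int, length: int, used: set[int]
) -> np.ndarray:
    """k distinct 1-based positions not already in ``used`` (infinite sites)."""
    out = np.empty(k, dtype=np.int64)
    i = 0
    while i < k:
        p = int(rng.integers(1, length + 1))
        if p not in used:
            used.add(p)
            out[i] = p
            i += 1
    return out


class Simulator:
    """Runs one configured scenario; ``run()`` returns matrices + truth."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.positions = np.empty(0, dtype=np.int64)
        self.used_positions: set[int] = set()
        self.pops: list[_Population] = []
        self.sweep_col: int = -1  # column index of the sweep site, -1 = none

    # -- per-generation mechanics -------------------------------------------------

    def _next_generation(self, pop: _Population, fitness: np.ndarray | None) -> None:
        """One Wright–Fisher generation in place: selection, recombination,
        then mutation (new columns are appended to every population)."""
        rng = self.rng
        cfg = self.cfg
        n = pop.n_dip
        if fitness is None:
            parents = rng.integers(0, n, size=2 * n)
        else:
            w = fitness / fitness.sum()
            parents = rng.choice(n, size=2 * n, p=w)
        hap_choice = rng.integers(0, 2, size=2 * n)
        base = 2 * parents + hap_choice
        children = pop.haps[base]

        p_rec = min(1.0, cfg.r * cfg.length)
        if p_rec > 0:
            rec = rng.random(2 * n) < p_rec
            k = int(rec.sum())
            if k:
                other = 2 * parents[rec] + (1 - hap_choice[rec])
                breaks = rng.integers(1, cfg.length + 1, size=k)
                left = self.positions[None, :] < breaks[:, None]
                children[rec] = np.where(left, children[rec], pop.haps[other])
        pop.haps = children

        n_mut = rng.poisson(2 * n * cfg.mu * cfg.length)
        if n_mut:
            new_pos = _fresh_positions(rng, n_mut, cfg.length, self.used_positions)
            self.positions = np.concatenate([self.positions, new_pos])
            for p in self.pops:
                block = np.zeros((p.haps.shape[0], n_mut), dtype=np.uint8)
                if p is pop:
                    block[rng.integers(0, 2 * n, size=n_mut), np.arange(n_mut)] = 1
                p.haps = np.concatenate([p.haps, block], axis=1)

    def _prune(self) -> None:
        """Drop columns lost or fixed across all populations (the sweep column
        is always kept while a sweep is registered)."""
        total = sum(p.haps.sum(axis=0, dtype=np.int64) for p in self.pops)
        n_hap_total = sum(p.haps.shape[0] for p in self.pops)
        keep = (total > 0) & (total < n_hap_total)
        if self.sweep_col >= 0:
            keep[self.sweep_col] = True
        if keep.all():
            return
        dropped_pos = self.positions[~keep]
        self.used_positions.difference_update(int(x) for x in dropped_pos)
        idx = np.flatnonzero(keep)
        if self.sweep_col >= 0:
            self.sweep_col = int(np.searchsorted(idx, self.sweep_col))
        self.positions = self.positions[idx]
        for p in self.pops:
            p.haps = p.haps[:, idx]

    def _sweep_fitness(self, pop: _Population, s: float) -> np.ndarray:
        dos = (
            pop.haps[0::2, self.sweep_col].astype(np.float64)
            + pop.haps[1::2, self.sweep_col]
        )
        return 1.0 + 0.5 * s * dos

    def _sweep_freq(self, pop: _Population) -> float:
        return float(pop.haps[:, self.sweep_col].mean())

    # -- scenario phases ----------------------------------------------------------

    def run(self) -> tuple[dict[str, HaplotypeMatrix], TruthRecord]:
        cfg = self.cfg
        rng = self.rng
        n_hap = 2 * cfg.n_e
        theta = 4 * cfg.n_e * cfg.mu * cfg.length

        haps, positions = _stationary_init(rng, n_hap, theta, cfg.length)
        self.positions = positions
        self.used_positions = set(int(x) for x in positions)
        self.pops = [_Population(haps)]

        burn = cfg.burn_in_gens if cfg.burn_in_gens is not None else cfg.n_e
        for g in range(burn):
            self._next_generation(self.pops[0], None)
            if g % 10 == 9:
                self._prune()
        self._prune()

        truth = TruthRecord(
            seed=cfg.seed,
            n_pops=cfg.n_pops,
            split_gens_nominal=cfg.split_gens,
            split_gens_realized=0,
        )

        if cfg.n_pops >= 2:
            for _ in range(cfg.n_pops - 1):
                self.pops.append(self.pops[0].copy())
            realized = self._split_phase(truth)
            truth.split_gens_realized = realized
        elif cfg.sweep is not None:
            self._single_pop_sweep(truth)

        if cfg.admix is not None:
            self._admix_pulse(truth)

        return self._sample_output(truth)

    def _inject_sweep(self, sw: SweepSpec) -> None:
        """Seed a single-origin (hard) sweep: the new allele arises on one
        donor haplotype, and any additional starting copies (start_freq > 1/2N)
        are clones of that donor — emulating the allele having drifted to the
        start frequency on its ancestral background before selection begins.
        Recombination during the sweep then diversifies the flanks."""
        pop = self.pops[sw.population]
        n_hap = pop.haps.shape[0]
        pos = sw.position if sw.position is not None else self.cfg.length // 2
        if int(pos) in self.used_positions:
            pos = int(_fresh_positions(self.rng, 1, self.cfg.length, self.used_positions)[0])
        else:
            self.used_positions.add(int(pos))
        k = max(1, round(sw.start_freq * n_hap))
        carriers = self.rng.choice(n_hap, size=k, replace=False)
        donor = carriers[0]
        pop.haps[carriers[1:], :] = pop.haps[donor, :]
        self.positions = np.concatenate([self.positions, [pos]])
        for i, p in enumerate(self.pops):
            col = np.zeros((p.haps.shape[0], 1), dtype=np.uint8)
            if i == sw.population:
                col[carriers, 0] = 1
            p.haps = np.concatenate([p.haps, col], axis=1)
        self.sweep_col = len(self.positions) - 1

    def _split_phase(self, truth: TruthRecord) -> int:
        """Post-split evolution of all populations, with the optional sweep in
        one of them. The sweep allele enters at the split; selection runs until
        the end-condition frequency, restarting from the split state on loss.
        All populations evolve the same realized number of generations."""
        cfg = self.cfg
        sw = cfg.sweep
        if sw is None:
            for g in range(cfg.split_gens):
                for p in self.pops:
                    self._next_generation(p, None)
                if g % 10 == 9:
                    self._prune()
            self._prune()
            return cfg.split_gens

        self._inject_sweep(sw)
        truth.sweep_position = int(self.positions[self.sweep_col])
        truth.sweep_s = sw.s
        truth.sweep_population = sw.population

        snapshot = ([p.copy() for p in self.pops], self.positions.copy(),
                    set(self.used_positions), self.sweep_col)
        restarts = 0
        max_extra = 40 * cfg.n_e  # hard cap on total post-split generations
        while True:
            gen = 0
            reached = False
            lost = False
            while gen < cfg.split_gens or (not reached and gen < max_extra):
                swept_pop = self.pops[sw.population]
                fit = None if reached else self._sweep_fitness(swept_pop, sw.s)
                for i, p in enumerate(self.pops):
                    self._next_generation(p, fit if i == sw.population else None)
                gen += 1
                f = self._sweep_freq(swept_pop)
                if not reached and f >= sw.end_freq:
                    reached = True
                if f == 0.0:
                    lost = True
                    break
                if gen % 10 == 0:
                    self._prune()
            if reached and not lost:
                break
            restarts += 1
            if restarts > sw.max_restarts:
                raise SweepLostError(
                    f"sweep lost {restarts} times (s={sw.s}, start_freq={sw.start_freq})"
                )
            pops, pos, used, col = snapshot
            self.pops = [p.copy() for p in pops]
            self.positions = pos.copy()
            self.used_positions = set(used)
            self.sweep_col = col
        self._prune()
        truth.sweep_restarts = restarts
        for i, p in enumerate(self.pops):
            truth.sweep_freq[f"pop{i}"] = self._sweep_freq(p)
        return gen

    def _single_pop_sweep(self, truth: TruthRecord) -> None:
        cfg = self.cfg
        sw = cfg.sweep
        self._inject_sweep(sw)
        truth.sweep_position = int(self.positions[self.sweep_col])
        truth.sweep_s = sw.s
        truth.sweep_population = 0
        snapshot = (self.pops[0].copy(), self.positions.copy(), set(self.used_positions))
        restarts = 0
        while True:
            pop = self.pops[0]
            f = self._sweep_freq(pop)
            gens = 0
            while 0.0 < f < sw.end_freq and gens < 40 * cfg.n_e:
                self._next_generation(pop, self._sweep_fitness(pop, sw.s))
                f = self._sweep_freq(pop)
                gens += 1
                if gens % 10 == 0:
                    self._prune()
            if f >= sw.end_freq:
                break
            restarts += 1
            if restarts > sw.max_restarts:
                raise SweepLostError(f"sweep lost {restarts} times")
            p0, pos, used = snapshot
            self.pops = [p0.copy()]
            self.positions = pos.copy()
            self.used_positions = set(used)
            self.sweep_col = len(pos) - 1
        self._prune()
        truth.sweep_freq["pop0"] = self._sweep_freq(self.pops[0])
        truth.split_gens_realized = 0

    def _admix_pulse(self, truth: TruthRecord) -> None:
        """Found a new population by drawing each haplotype from source A with
        probability alpha (else source B), then drift for gens_after."""
        ad = self.cfg.admix
        a, b = self.pops[ad.source_a], self.pops[ad.source_b]
        n_hap = a.haps.shape[0]
        from_a = self.rng.random(n_hap) < ad.alpha
        rows_a = self.rng.integers(0, n_hap, size=n_hap)
        rows_b = self.rng.integers(0, n_hap, size=n_hap)
        haps = np.where(from_a[:, None], a.haps[rows_a], b.haps[rows_b])
        target = _Population(haps.astype(np.uint8))
        self.pops.append(target)
        for _ in range(ad.gens_after):
            for p in self.pops:
                self._next_generation(p, None)
        self._prune()
        truth.alpha = ad.alpha

    # -- output -------------------------------------------------------------------

    def _sample_output(
        self, truth: TruthRecord
    ) -> tuple[dict[str, HaplotypeMatrix], TruthRecord]:
        cfg = self.cfg
        rng = self.rng
        order = np.argsort(self.positions, kind="stable")
        positions = self.positions[order]

        sampled: dict[str, np.ndarray] = {}
        pop_labels = [f"pop{i}" for i in range(len(self.pops))]
        for label, pop in zip(pop_labels, self.pops):
            rows = rng.choice(pop.haps.shape[0], size=2 * cfg.n_samples, replace=False)
            sampled[label] = pop.haps[rows][:, order]

        # keep sites segregating in the pooled sample
        total = sum(h.sum(axis=0, dtype=np.int64) for h in sampled.values())
        n_tot = sum(h.shape[0] for h in sampled.values())
        keep = (total > 0) & (total < n_tot)
        positions = positions[keep]
        matrices: dict[str, HaplotypeMatrix] = {}
        for label in pop_labels:
            haps = sampled[label][:, keep]
            samples = [f"{label}_s{i}" for i in range(cfg.n_samples)]
            matrices[label] = HaplotypeMatrix(
                haps, positions.copy(), samples, np.repeat("1", len(positions))
            )
            if self.sweep_col >= 0:
                j = np.searchsorted(positions, truth.sweep_position)
                if j < len(positions) and positions[j] == truth.sweep_position:
                    truth.sweep_freq[f"{label}_sample"] = float(haps[:, j].mean())
        truth.n_sites_out = len(positions)
        return matrices, truth


def simulate(cfg: SimConfig, out_dir: str | Path | None = None):
    """Run one scenario; optionally write VCF + pops.tsv + truth.json +
    genes.bed under ``out_dir``. Returns (matrices by population, truth)."""
    matrices, truth = Simulator(cfg).run()
    if out_dir is not None:
        write_outputs(matrices, truth, cfg, out_dir)
    return matrices, truth


def matrices_to_tables(
    matrices: dict[str, HaplotypeMatrix],
) -> tuple[SiteTable, GenotypeMatrix, HaplotypeMatrix, PopulationMap]:
    """Merge per-population matrices (identical site sets) into pooled
    SiteTable/GenotypeMatrix/HaplotypeMatrix plus a PopulationMap."""
    labels = list(matrices)
    first = matrices[labels[0]]
    positions = first.positions
    df = pd.DataFrame(
        {
            "chrom": "1",
            "pos": positions,
            "id": ".",
            "ref": "A",
            "alt": "G",
            "ancestral": "A",
            "aa_fallback": False,
        }
    )
    sites = SiteTable(df)
    haps = np.concatenate([matrices[m].haplotypes for m in labels], axis=0)
    samples = [s for m in labels for s in matrices[m].samples]
    hm = HaplotypeMatrix(haps, positions.copy(), samples, np.repeat("1", len(positions)))
    gm = GenotypeMatrix(samples, hm.to_dosages())
    pmap = PopulationMap({s: m for m in labels for s in matrices[m].samples})
    return sites, gm, hm, pmap


def write_outputs(
    matrices: dict[str, HaplotypeMatrix],
    truth: TruthRecord,
    cfg: SimConfig,
    out_dir: str | Path,
    gene_bp: int = 20_000,
    gene_spacing: int = 40_000,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites, gm, hm, pmap = matrices_to_tables(matrices)
    write_vcf(out / "sim.vcf", sites, gm, hm)
    with open(out / "pops.tsv", "w") as fh:
        fh.write("sample\tpopulation\n")
        for s, p in pmap.assignments.items():
            fh.write(f"{s}\t{p}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(asdict(truth), fh, indent=2)
    make_gene_intervals(cfg.length, gene_bp, gene_spacing).to_csv(
        out / "genes.bed", sep="\t", index=False, header=False
    )


def make_gene_intervals(
    length: int, gene_bp: int = 20_000, spacing: int = 40_000, chrom: str = "1"
) -> pd.DataFrame:
    """Uniform synthetic gene annotation: ``gene_bp``-long genes every
    ``spacing`` bp (0-based half-open), named g0, g1, ..."""
    starts = np.arange(0, max(length - gene_bp, 0) + 1, spacing, dtype=np.int64)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + gene_bp,
            "name": [f"g{i}" for i in range(len(starts))],
        }
    )


def simulate_frequencies(
    n_snps: int = 50_000,
    n_e: int = 500,
    split_gens: int = 50,
    alpha: float | None = 0.5,
    target_extra_gens: int = 10,
    target_drift_gens: int | None = None,
    sample_chroms: int = 100,
    genome_length: int = 2_000_000_000,
    seed: int = 0,
) -> dict:
    """Frequency-only Wright–Fisher drift for f3-scale experiments.

    Sites are unlinked: an ancestral frequency is drawn per site from the
    neutral spectrum (density ∝ 1/p on the polymorphic range), two source
    populations A and B drift independently for ``split_gens`` binomial WF
    generations, and the target C is founded either as an alpha:1-alpha pulse
    of A and B (``alpha`` given) followed by ``target_extra_gens`` of drift, or
    as a further-drifted copy of A (``alpha=None``, drifting
    ``target_drift_gens``, default ``split_gens``). Sampled frequencies use
    ``sample_chroms`` binomial draws per population. Positions are uniform over
    ``genome_length`` so block-jackknife blocks are non-trivial.

    Returns dict with freq arrays (A, B, C), n_c, positions, alpha.
    """
    rng = np.random.default_rng(seed)
    two_n = 2 * n_e
    # neutral spectrum on the grid i/2N, weight 1/i
    i = np.arange(1, two_n)
    w = 1.0 / i
    p0 = rng.choice(i, size=n_snps, p=w / w.sum()) / two_n

    def drift(p: np.ndarray, gens: int) -> np.ndarray:
        q = p.copy()
        for _ in range(gens):
            q = rng.binomial(two_n, q) / two_n
        return q

    pa = drift(p0, split_gens)
    pb = drift(p0, split_gens)
    if alpha is not None:
        pc = drift(alpha * pa + (1 - alpha) * pb, target_extra_gens)
    else:
        pc = drift(pa, target_drift_gens if target_drift_gens is not None else split_gens)

    fa = rng.binomial(sample_chroms, pa) / sample_chroms
    fb = rng.binomial(sample_chroms, pb) / sample_chroms
    fc = rng.binomial(sample_chroms, pc) / sample_chroms
    positions = np.sort(rng.integers(1, genome_length + 1, size=n_snps))
    return {
        "freq_a": fa,
        "freq_b": fb,
        "freq_c": fc,
        "n_c": sample_chroms,
        "positions": positions,
        "alpha": alpha,
    }


# -- hand-checkable toy fixtures ---------------------------------------------------


def make_toy_fixtures() -> dict:
    """Small deterministic fixtures used by hand-enumeration tests.

    ``qc``: 10 sites x 10 diploids engineered so the QC cascade removes
    2 (missingness) + 3 (minor allele count) + 0 (MAF) + 1 (HWE) and keeps 4.
    ``ehh``: the four haplotypes {00, 01, 10, 11}.
    ``genes``: 5 genes against 3 contiguous 100 kb windows.
    """
    M = -1
    # built sites-as-rows for legibility, transposed to samples x sites below;
    # 11 diploids: the smallest cohort where the exact HWE test can reach p < 0.001
    by_site = np.array(
        [
            [M, M, 1, 1, 0, 1, 0, 1, 0, 1, 1],  # 2/11 missing -> missingness filter
            [1, 1, M, M, 1, 0, 1, 1, 0, 0, 1],  # 2/11 missing -> missingness filter
            [0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0],  # mac 1 -> minor-allele-count filter
            [0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0],  # mac 2 -> minor-allele-count filter
            [0, 0, 1, 0, 0, 0, 0, 0, 1, 0, 0],  # mac 2 -> minor-allele-count filter
            [0, 0, 2, 0, 2, 0, 2, 2, 0, 2, 0],  # (6 homR, 0 het, 5 homA): p=7.1e-4 -> HWE filter
            [0, 1, 1, 2, 1, 0, 1, 2, 0, 1, 0],  # survivor, (4,5,2)
            [1, 2, 0, 1, 1, 2, 1, 0, 2, 1, 0],  # survivor, (3,5,3)
            [0, 1, 1, 2, 0, 1, 0, 2, 1, 0, 0],  # survivor, (5,4,2)
            [1, 1, 0, 1, 2, 1, 0, 1, 0, 1, 0],  # survivor, (4,6,1)
        ],
        dtype=np.int8,
    )
    dosages = by_site.T.copy()  # samples x sites; each sample <= 10% missing
    samples = [f"t{i}" for i in range(11)]
    gm = GenotypeMatrix(samples, dosages)
    st = SiteTable(
        pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, 11) * 1000,
                "id": ".",
                "ref": "A",
                "alt": "G",
                "ancestral": "A",
                "aa_fallback": False,
            }
        )
    )

    ehh_hm = HaplotypeMatrix(
        np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8),
        np.array([1000, 2000], dtype=np.int64),
        ["e0", "e1"],
        np.array(["1", "1"]),
    )

    genes = pd.DataFrame(
        {
            "chrom": "1",
            "start": [10, 95_000, 150_000, 250_000, 300_000],
            "end": [20, 105_000, 160_000, 251_000, 310_000],
            "name": ["g_left", "g_span", "g_mid", "g_right", "g_out"],
        }
    )
    windows = pd.DataFrame(
        {"chrom": "1", "start": [0, 100_000, 200_000], "end": [100_000, 200_000, 300_000]}
    )
    return {"qc": (gm, st), "ehh": ehh_hm, "genes": genes, "windows": windows}
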