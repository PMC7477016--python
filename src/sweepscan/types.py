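"""Core in-memory containers shared across the pipeline.

The pipeline works on three aligned views of a phased, bi-allelic SNP panel:

* :class:`SiteTable` — per-site metadata (coordinates, alleles, ancestral state),
* :class:`GenotypeMatrix` — diploid dosages (0/1/2, ``-1`` missing), samples x sites,
* :class:`HaplotypeMatrix` — phased binary haplotypes, ``2N x L``.

All three are thin dataclasses over numpy arrays / pandas frames; they carry
their invariants as cheap ``validate()`` checks rather than enforcing them on
every mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # dosage marker for an uncalled genotype


@dataclass
class SiteTable:
    """Per-site metadata for a bi-allelic SNP panel.

    ``pos`` is 1-based inclusive (VCF convention); all window arithmetic in the
    pipeline converts to 0-based half-open at the point of use. ``ancestral``
    holds the ancestral base when known (equal to ``ref`` or ``alt``) or ``"."``;
    ``aa_fallback`` records sites where polarity fell back to ref=ancestral.
    """

    df: pd.DataFrame  # columns: chrom, pos, id, ref, alt, ancestral, aa_fallback

    REQUIRED = ("chrom", "pos", "id", "ref", "alt", "ancestral", "aa_fallback")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"SiteTable missing columns: {missing}")

    @property
    def n_sites(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    def validate(self) -> None:
        for _, sub in self.df.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError("positions not strictly increasing within chromosome")
        known = self.df["ancestral"] != "."
        ok = (self.df.loc[known, "ancestral"] == self.df.loc[known, "ref"]) | (
            self.df.loc[known, "ancestral"] == self.df.loc[known, "alt"]
        )
        if not ok.all():
            raise ValueError("ancestral allele matches neither ref nor alt at some site")

    def subset(self, idx: np.ndarray) -> "SiteTable":
        return SiteTable(self.df.iloc[np.asarray(idx)].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosages, one row per sample, one column per site."""

    samples: list[str]
    dosages: np.ndarray  # int8, samples x sites; MISSING = -1

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.samples):
            raise ValueError("dosage matrix shape does not match sample list")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def called_mask(self) -> np.ndarray:
        return self.dosages != MISSING

    def missing_rate(self) -> float:
        return float(np.mean(self.dosages == MISSING))

    def subset(self, sample_idx=None, site_idx=None) -> "GenotypeMatrix":
        d = self.dosages
        samples = self.samples
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx, :]
            samples = [self.samples[i] for i in sample_idx]
        if site_idx is not None:
            d = d[:, np.asarray(site_idx)]
        return GenotypeMatrix(samples, d.copy())


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes: rows ``2k`` and ``2k+1`` belong to sample ``k``.

    Allele coding follows the panel's polarity policy: 0 = ancestral (or ref
    where the ancestral state is unknown), 1 = the other allele.
    """

    haplotypes: np.ndarray  # uint8, 2N x L
    positions: np.ndarray  # int64, bp (1-based)
    samples: list[str]
    chrom: np.ndarray | None = None  # per-site chromosome labels (optional)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype row count must be twice the sample count")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("haplotype column count must match positions")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def sample_of_haplotype(self, h: int) -> str:
        return self.samples[h // 2]

    def derived_counts(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(np.int64)

    def derived_freq(self) -> np.ndarray:
        return self.derived_counts() / self.n_haplotypes

    def to_dosages(self) -> np.ndarray:
        """Collapse phased haplotypes to diploid dosages (no missingness)."""
        n = len(self.samples)
        return (
            self.haplotypes.reshape(n, 2, self.n_sites).sum(axis=1).astype(np.int8)
        )

    def subset_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        return HaplotypeMatrix(
            self.haplotypes[:, idx].copy(),
            self.positions[idx].copy(),
            list(self.samples),
            None if self.chrom is None else self.chrom[idx].copy(),
        )

    def subset_samples(self, sample_idx: np.ndarray) -> "HaplotypeMatrix":
        sample_idx = np.asarray(sample_idx)
        hap_idx = np.empty(2 * len(sample_idx), dtype=np.int64)
        hap_idx[0::2] = 2 * sample_idx
        hap_idx[1::2] = 2 * sample_idx + 1
        return HaplotypeMatrix(
            self.haplotypes[hap_idx, :].copy(),
            self.positions.copy(),
            [self.samples[i] for i in sample_idx],
            None if self.chrom is None else self.chrom.copy(),
        )


@dataclass
class PopulationMap:
    """Mapping sample id -> population label."""

    assignments: dict[str, str] = field(default_factory=dict)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == pop]

    def indices_of(self, pop: str, samples: list[str]) -> np.ndarray:
        """Row indices (into ``samples``) of the members of ``pop``."""
        want = set(self.samples_of(pop))
        return np.array([i for i, s in enumerate(samples) if s in want], dtype=np.int64)

    def __getitem__(self, sample: str) -> str:
        return self.assignments[sample]

    def __len__(self) -> int:
        return len(self.assignments)
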