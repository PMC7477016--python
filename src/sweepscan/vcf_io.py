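"""Reading and writing the formats the pipeline touches: VCF, BED, TSV.

VCF parsing is delegated to cyvcf2; only phased, bi-allelic SNP records are
turned into matrices. Multi-allelic and non-SNP records are dropped (never
decomposed) and the drop count is reported, matching a pipeline that analyses
bi-allelic loci only. Coordinates are stored 1-based inclusive (VCF
convention); BED output is written 0-based half-open.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import MISSING, GenotypeMatrix, HaplotypeMatrix, PopulationMap, SiteTable

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class VcfFormatError(ValueError):
    """The VCF lacks a structural prerequisite (e.g. no GT field)."""


class PhasingError(ValueError):
    """Phased haplotype output was requested but genotypes are unphased."""


@dataclass
class ReadResult:
    sites: SiteTable
    genotypes: GenotypeMatrix
    haplotypes: HaplotypeMatrix | None
    n_dropped: int  # non-bi-allelic / non-SNP records skipped


def read_vcf(
    path: str | Path,
    samples: list[str] | None = None,
    region: str | None = None,
    require_phased: bool = True,
) -> ReadResult:
    """Read a VCF into the pipeline's matrices.

    Parameters
    ----------
    path:
        VCF 4.x file, plain or bgzipped (a region query needs an index).
    samples:
        Optional subset of sample ids to load, in the order given.
    region:
        Optional ``chrom:start-end`` query (1-based inclusive, cyvcf2
        semantics).
    require_phased:
        When True (default) every genotype must use the ``|`` separator and a
        haplotype matrix is returned; the first unphased record raises
        :class:`PhasingError`. When False the haplotype matrix is ``None`` and
        ``/`` separators are tolerated.

    Returns
    -------
    ReadResult
        Site table, genotype matrix, haplotype matrix (or None), and the
        number of dropped non-bi-allelic / non-SNP records.
    """
    vcf = VCF(str(path), samples=samples, gts012=True)
    if samples is not None:
        got = list(vcf.samples)
        missing = set(samples) - set(got)
        if missing:
            raise VcfFormatError(f"samples not in VCF: {sorted(missing)}")
    sample_names = list(vcf.samples)
    n = len(sample_names)

    rows = []
    dosage_rows = []
    hap_rows = []
    n_dropped = 0

    iterator = vcf(region) if region else vcf
    for var in iterator:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        gt = var.genotype.array()  # n x 3: allele1, allele2, phased flag
        if gt is None or gt.shape[1] < 3:
            raise VcfFormatError(f"missing GT field at {var.CHROM}:{var.POS}")
        a1 = gt[:, 0].astype(np.int8)
        a2 = gt[:, 1].astype(np.int8)
        called = (a1 >= 0) & (a2 >= 0)
        if require_phased:
            if not called.all():
                bad = sample_names[int(np.flatnonzero(~called)[0])]
                raise PhasingError(
                    f"missing genotype for sample {bad} at {var.CHROM}:{var.POS}; "
                    "haplotype matrices cannot represent missing calls"
                )
            unphased = called & (gt[:, 2] == 0)
            if unphased.any():
                bad = sample_names[int(np.flatnonzero(unphased)[0])]
                raise PhasingError(
                    f"unphased genotype for sample {bad} at {var.CHROM}:{var.POS}; "
                    "phased input required for haplotype statistics"
                )
            hap_rows.append(np.stack([a1, a2], axis=1).reshape(-1))
        dos = np.where(called, a1 + a2, MISSING).astype(np.int8)
        dosage_rows.append(dos)
        aa = var.INFO.get("AA")
        aa = aa.upper() if isinstance(aa, str) else "."
        fallback = aa not in (var.REF.upper(), var.ALT[0].upper())
        rows.append(
            (
                var.CHROM,
                var.POS,
                var.ID or ".",
                var.REF.upper(),
                var.ALT[0].upper(),
                var.REF.upper() if fallback else aa,
                fallback,
            )
        )
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d non-bi-allelic/non-SNP records", n_dropped)

    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "ref", "alt", "ancestral", "aa_fallback"]
    )
    sites = SiteTable(df)
    dosages = (
        np.stack(dosage_rows, axis=1) if dosage_rows else np.zeros((n, 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(sample_names, dosages)

    hm = None
    if require_phased:
        if hap_rows:
            haps = np.stack(hap_rows, axis=1).astype(np.uint8)  # (2n) x L
        else:
            haps = np.zeros((2 * n, 0), dtype=np.uint8)
        # polarity: 1 = non-ancestral allele; flip columns where ancestral == alt
        flip = (df["ancestral"] == df["alt"]).to_numpy()
        if flip.any():
            haps[:, flip] = 1 - haps[:, flip]
        hm = HaplotypeMatrix(
            haps,
            df["pos"].to_numpy(np.int64),
            sample_names,
            df["chrom"].to_numpy(),
        )
    return ReadResult(sites, gm, hm, n_dropped)


def write_vcf(
    path: str | Path,
    sites: SiteTable,
    gm: GenotypeMatrix,
    hm: HaplotypeMatrix | None = None,
) -> None:
    """Write a plain-text VCF 4.2 (gzipped when the path ends in .gz).

    When a haplotype matrix is given, genotypes are written phased from it
    (converting polarity back to ref/alt coding); otherwise unphased genotypes
    are reconstructed from dosages.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    df = sites.df
    flip = (df["ancestral"] == df["alt"]).to_numpy()
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(df["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j in range(sites.n_sites):
            r = df.iloc[j]
            info = f"AA={r.ancestral}" if r.ancestral != "." else "AA=."
            if hm is not None:
                col = hm.haplotypes[:, j]
                if flip[j]:
                    col = 1 - col
                gts = "\t".join(
                    f"{col[2 * k]}|{col[2 * k + 1]}" for k in range(len(gm.samples))
                )
            else:
                dos = gm.dosages[:, j]
                gts = "\t".join(
                    "./." if d == MISSING else ("0/0", "0/1", "1/1")[d] for d in dos
                )
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.id}\t{r.ref}\t{r.alt}\t.\t.\t{info}\tGT\t{gts}\n"
            )


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a frame of (chrom, start, end, name).

    Coordinates stay 0-based half-open. Intervals are returned sorted by
    (chrom, start); overlapping intervals are both retained.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"malformed interval {chrom}:{start}-{end} (start >= end)")
            name = parts[3] if len(parts) > 3 else "."
            rows.append((chrom, start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a two-column sample<TAB>population file (header optional)."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"population map line {i + 1} lacks two columns")
            if i == 0 and parts[0].lower() in ("sample", "sample_id", "id"):
                continue
            assignments[parts[0]] = parts[1]
    return PopulationMap(assignments)


def write_table(records: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write records as TSV (with header) or BED (0-based half-open, no header).

    BED output expects ``chrom``/``start``/``end`` columns already 0-based
    half-open; any further columns are appended in order.
    """
    path = Path(path)
    if format == "tsv":
        records.to_csv(path, sep="\t", index=False)
    elif format == "bed":
        cols = ["chrom", "start", "end"] + [
            c for c in records.columns if c not in ("chrom", "start", "end")
        ]
        records[cols].to_csv(path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown table format: {format}")
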