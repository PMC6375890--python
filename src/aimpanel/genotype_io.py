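"""Genotype and admixture matrix containers plus PLINK / Q-P file I/O.

The central container is :class:`GenotypeMatrix`: an individuals x SNPs
table of alternate-allele counts in {0, 1, 2} with a dedicated missing
sentinel (:data:`MISSING`, never 0 — silent zero-imputation would corrupt
allele frequencies downstream). Family IDs double as population labels,
the convention of PLINK-era population-genetics pipelines.

Supported formats:

* PLINK text (.ped/.map),
* PLINK 1 binary (.bed/.bim/.fam, SNP-major only),
* ADMIXTURE-style whitespace-separated .Q / .P matrices.

All parsers are hand-rolled: the 2-bit .bed codec is implemented directly
from the published table so it can be checked bit-for-bit in tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

#: Out-of-band sentinel for a missing diploid genotype call.
MISSING: int = -1

# PLINK 1 .bed magic bytes and the SNP-major mode byte.
_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# 2-bit .bed codes (SNP-major), decoded to copies of allele-1 (A1):
#   00 -> homozygous A1 (2 copies), 01 -> missing,
#   10 -> heterozygous (1 copy),    11 -> homozygous A2 (0 copies).
# We designate A1 as the alternate allele, so the decoded value is the
# alternate-allele count directly.
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised for malformed PLINK text or binary input."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes as alternate-allele counts.

    Parameters
    ----------
    individual_ids : list of str
        Unique within-family sample identifiers (IID).
    family_ids : list of str
        Family identifiers (FID); used throughout as the population label.
    snp_ids : list of str
        Unique marker identifiers.
    chromosomes : list of str
        Chromosome code per SNP.
    positions : list of int
        1-based physical positions per SNP.
    genotypes : ndarray of shape (n_individuals, n_snps), int8
        Alternate-allele counts in {0, 1, 2} or ``MISSING``.
    ref_alleles, alt_alleles : list of str
        Per-SNP allele labels; counts refer to the alternate allele. All
        statistics in this package are symmetric under allele relabelling,
        so orientation never changes a result.
    """

    individual_ids: list[str]
    family_ids: list[str]
    snp_ids: list[str]
    chromosomes: list[str]
    positions: list[int]
    genotypes: np.ndarray
    ref_alleles: list[str] = field(default_factory=list)
    alt_alleles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = self.genotypes.shape
        if len(self.individual_ids) != n or len(self.family_ids) != n:
            raise ValueError("individual/family id count does not match genotype rows")
        if len(self.snp_ids) != m or len(self.chromosomes) != m or len(self.positions) != m:
            raise ValueError("SNP metadata length does not match genotype columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids must be unique")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP id")
        if not self.ref_alleles:
            self.ref_alleles = ["A"] * m
        if not self.alt_alleles:
            self.alt_alleles = ["B"] * m
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2} or MISSING")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the call is missing."""
        return self.genotypes == MISSING

    def snp_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snp_ids)}


@dataclass
class QMatrix:
    """Admixture proportions: individuals x K, rows on the simplex."""

    individual_ids: list[str]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 2:
            raise ValueError("Q must be 2-dimensional")
        if len(self.individual_ids) != self.proportions.shape[0]:
            raise ValueError("id count does not match Q rows")
        if np.any(self.proportions < -1e-9):
            raise ValueError("Q entries must be non-negative")
        if not np.allclose(self.proportions.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1 within 1e-6")

    @property
    def K(self) -> int:
        return self.proportions.shape[1]


@dataclass
class PMatrix:
    """Cluster-specific allele frequencies: SNPs x K, entries in [0, 1]."""

    snp_ids: list[str]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.ndim != 2:
            raise ValueError("P must be 2-dimensional")
        if len(self.snp_ids) != self.frequencies.shape[0]:
            raise ValueError("id count does not match P rows")
        if np.any(self.frequencies < -1e-12) or np.any(self.frequencies > 1 + 1e-12):
            raise ValueError("P entries must lie in [0, 1]")
        self.frequencies = np.clip(self.frequencies, 0.0, 1.0)

    @property
    def K(self) -> int:
        return self.frequencies.shape[1]


# ---------------------------------------------------------------------------
# PLINK text (.ped / .map)
# ---------------------------------------------------------------------------

def read_plink_text(ped_path: str | os.PathLike, map_path: str | os.PathLike) -> GenotypeMatrix:
    """Read a PLINK text fileset into a :class:`GenotypeMatrix`.

    The alternate allele at each SNP is the lexicographically second
    observed allele (a monomorphic SNP keeps its single observed allele as
    reference and scores 0 copies everywhere). ``0 0`` allele pairs decode
    to :data:`MISSING`.
    """
    snp_ids: list[str] = []
    chromosomes: list[str] = []
    positions: list[int] = []
    with open(map_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) != 4:
                raise PlinkFormatError(f"{map_path}: line {lineno}: expected 4 columns, got {len(parts)}")
            chromosomes.append(parts[0])
            snp_ids.append(parts[1])
            positions.append(int(parts[3]))
    if len(set(snp_ids)) != len(snp_ids):
        raise PlinkFormatError(f"{map_path}: duplicate SNP id")
    m = len(snp_ids)

    family_ids: list[str] = []
    individual_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields "
                    f"(6 header + 2 alleles x {m} SNPs), got {len(parts)}"
                )
            family_ids.append(parts[0])
            individual_ids.append(parts[1])
            allele_rows.append(np.array(parts[6:], dtype=object).reshape(m, 2))
    alleles = np.stack(allele_rows) if allele_rows else np.empty((0, m, 2), dtype=object)

    n = len(individual_ids)
    genotypes = np.full((n, m), MISSING, dtype=np.int8)
    ref_alleles: list[str] = []
    alt_alleles: list[str] = []
    for j in range(m):
        col = alleles[:, j, :] if n else np.empty((0, 2), dtype=object)
        observed = sorted({a for a in col.ravel() if a != "0"})
        if len(observed) > 2:
            raise PlinkFormatError(f"{ped_path}: SNP {snp_ids[j]} has >2 alleles: {observed}")
        if len(observed) == 2:
            ref, alt = observed
        elif len(observed) == 1:
            ref, alt = observed[0], observed[0]
        else:
            ref, alt = "0", "0"
        ref_alleles.append(ref)
        alt_alleles.append(alt)
        if n:
            miss = (col == "0").any(axis=1)
            count = (col == alt).sum(axis=1)
            if len(observed) == 1:
                count = np.zeros(n, dtype=np.int8)
            genotypes[:, j] = np.where(miss, MISSING, count)

    return GenotypeMatrix(
        individual_ids=individual_ids,
        family_ids=family_ids,
        snp_ids=snp_ids,
        chromosomes=chromosomes,
        positions=positions,
        genotypes=genotypes,
        ref_alleles=ref_alleles,
        alt_alleles=alt_alleles,
    )


def write_plink_text(G: GenotypeMatrix, ped_path: str | os.PathLike, map_path: str | os.PathLike) -> None:
    """Write a PLINK text fileset; inverse of :func:`read_plink_text`."""
    with open(map_path, "w") as fh:
        for chrom, sid, pos in zip(G.chromosomes, G.snp_ids, G.positions):
            fh.write(f"{chrom}\t{sid}\t0\t{pos}\n")
    ref = np.array(G.ref_alleles, dtype=object)
    alt = np.array(G.alt_alleles, dtype=object)
    with open(ped_path, "w") as fh:
        for i, (fid, iid) in enumerate(zip(G.family_ids, G.individual_ids)):
            row = G.genotypes[i]
            first = np.where(row >= 1, alt, ref)
            second = np.where(row == 2, alt, ref)
            first = np.where(row == MISSING, "0", first)
            second = np.where(row == MISSING, "0", second)
            fields = [fid, iid, "0", "0", "0", "-9"]
            for a, b in zip(first, second):
                fields.append(str(a))
                fields.append(str(b))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK 1 binary (.bed / .bim / .fam), SNP-major
# ---------------------------------------------------------------------------

def read_plink_binary(
    bed_path: str | os.PathLike,
    bim_path: str | os.PathLike,
    fam_path: str | os.PathLike,
) -> GenotypeMatrix:
    """Read a PLINK 1 binary fileset (SNP-major .bed only).

    Allele-1 (the fifth .bim column) is taken as the alternate allele, so
    the 2-bit code 00 (homozygous allele-1) decodes to 2 alternate copies.
    """
    snp_ids, chromosomes, positions, alt_alleles, ref_alleles = [], [], [], [], []
    with open(bim_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) != 6:
                raise PlinkFormatError(f"{bim_path}: line {lineno}: expected 6 columns")
            chromosomes.append(parts[0])
            snp_ids.append(parts[1])
            positions.append(int(parts[3]))
            alt_alleles.append(parts[4])
            ref_alleles.append(parts[5])
    if len(set(snp_ids)) != len(snp_ids):
        raise PlinkFormatError(f"{bim_path}: duplicate SNP id")

    family_ids, individual_ids = [], []
    with open(fam_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) != 6:
                raise PlinkFormatError(f"{fam_path}: line {lineno}: expected 6 columns")
            family_ids.append(parts[0])
            individual_ids.append(parts[1])

    n, m = len(individual_ids), len(snp_ids)
    bytes_per_snp = (n + 3) // 4
    with open(bed_path, "rb") as fh:
        data = fh.read()
    if len(data) < 3 or data[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: missing PLINK .bed magic bytes")
    if data[2] != _BED_SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: unsupported mode byte {data[2]:#04x} (individual-major .bed is not supported)")
    body = np.frombuffer(data, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise PlinkFormatError(
            f"{bed_path}: truncated or oversized body: expected {m * bytes_per_snp} bytes, got {body.size}"
        )
    blocks = body.reshape(m, bytes_per_snp)
    # Unpack 2-bit codes, lowest-order pair = first individual.
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    genotypes = _BED_DECODE[codes].T.copy()

    return GenotypeMatrix(
        individual_ids=individual_ids,
        family_ids=family_ids,
        snp_ids=snp_ids,
        chromosomes=chromosomes,
        positions=positions,
        genotypes=genotypes,
        ref_alleles=ref_alleles,
        alt_alleles=alt_alleles,
    )


def write_plink_binary(
    G: GenotypeMatrix,
    bed_path: str | os.PathLike,
    bim_path: str | os.PathLike,
    fam_path: str | os.PathLike,
) -> None:
    """Write a SNP-major PLINK 1 binary fileset; inverse of :func:`read_plink_binary`."""
    with open(bim_path, "w") as fh:
        for chrom, sid, pos, alt, ref in zip(G.chromosomes, G.snp_ids, G.positions, G.alt_alleles, G.ref_alleles):
            fh.write(f"{chrom}\t{sid}\t0\t{pos}\t{alt}\t{ref}\n")
    with open(fam_path, "w") as fh:
        for fid, iid in zip(G.family_ids, G.individual_ids):
            fh.write(f"{fid}\t{iid}\t0\t0\t0\t-9\n")

    n, m = G.n_individuals, G.n_snps
    bytes_per_snp = (n + 3) // 4
    # Map genotype values {0,1,2,MISSING} to 2-bit codes (inverse of _BED_DECODE).
    codes = np.empty((n, m), dtype=np.uint8)
    gt = G.genotypes
    codes[gt == 2] = 0b00
    codes[gt == MISSING] = 0b01
    codes[gt == 1] = 0b10
    codes[gt == 0] = 0b11
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    quads = padded.reshape(m, bytes_per_snp, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (quads << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# ADMIXTURE-style .Q / .P matrices
# ---------------------------------------------------------------------------

def write_qp(
    Q: QMatrix,
    P: PMatrix,
    prefix: str | os.PathLike,
) -> tuple[str, str]:
    """Write ``<prefix>.Q`` and ``<prefix>.P`` (whitespace-separated reals).

    One row per individual (Q) / SNP (P), mirroring ADMIXTURE's output
    conventions. Returns the two file paths.
    """
    if Q.K != P.K:
        raise ValueError(f"Q has K={Q.K} but P has K={P.K}")
    q_path, p_path = f"{prefix}.Q", f"{prefix}.P"
    np.savetxt(q_path, Q.proportions, fmt="%.6f")
    np.savetxt(p_path, P.frequencies, fmt="%.6f")
    return q_path, p_path


def read_qp(
    prefix: str | os.PathLike,
    individual_ids: list[str] | None = None,
    snp_ids: list[str] | None = None,
) -> tuple[QMatrix, PMatrix]:
    """Read ``<prefix>.Q`` / ``<prefix>.P`` written by :func:`write_qp`."""
    q = np.atleast_2d(np.loadtxt(f"{prefix}.Q", dtype=float))
    p = np.atleast_2d(np.loadtxt(f"{prefix}.P", dtype=float))
    if q.shape[1] != p.shape[1]:
        raise ValueError(f"K mismatch between Q ({q.shape[1]}) and P ({p.shape[1]})")
    # Renormalise rounding error from the fixed-precision text format.
    q = q / q.sum(axis=1, keepdims=True)
    if individual_ids is None:
        individual_ids = [f"ind{i}" for i in range(q.shape[0])]
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(p.shape[0])]
    return QMatrix(individual_ids, q), PMatrix(snp_ids, np.clip(p, 0.0, 1.0))
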