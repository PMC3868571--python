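"""Shared genomic data containers.

Coordinate conventions: all on-disk formats (VCF, GFF3, PLINK ``.hom``-style
TSV) use 1-based inclusive coordinates; internal interval arithmetic uses
0-based half-open intervals and converts at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# genotype codes used throughout
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

VALID_CODES = frozenset({HOM_REF, HET, HOM_ALT, MISSING})

AUTOSOME_EXCLUDE = frozenset({"X", "Y", "MT", "M", "chrX", "chrY", "chrM", "chrMT"})


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration."""


@dataclass
class VariantRecord:
    """One biallelic variant; ``pos`` is 1-based, alleles uppercase ACGT.

    ``genotypes`` (optional) is a per-sample vector of genotype codes aligned
    with the cohort's sample order.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray | None = None
    ancestral: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise DataError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def net_length_change(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass
class RohBlock:
    """One individual's contiguous homozygous interval (1-based inclusive)."""

    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int = 0
    n_het: int = 0

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise DataError(f"ROH start > end: {self}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, pos: int) -> bool:
        return self.start_bp <= pos <= self.end_bp


@dataclass
class GenotypeMatrix:
    """Per-individual biallelic genotype codes over ordered genomic sites.

    ``sites`` has columns chrom, pos, ref, alt (pos 1-based) and is strictly
    sorted by (chrom, pos); ``calls`` is (n_sites, n_samples) int8.
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise DataError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sites)}, {len(self.samples)})"
            )
        bad = set(np.unique(self.calls)) - VALID_CODES
        if bad:
            raise DataError(f"unknown genotype codes: {sorted(bad)}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        chroms = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        for i in range(1, len(pos)):
            if chroms[i] == chroms[i - 1] and pos[i] <= pos[i - 1]:
                raise DataError(
                    f"sites not strictly sorted at row {i} "
                    f"({chroms[i]}:{pos[i]})"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def variant(self, i: int) -> VariantRecord:
        row = self.sites.iloc[i]
        return VariantRecord(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            genotypes=self.calls[i],
        )

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous row slices per chromosome, in matrix order."""
        chroms = self.sites["chrom"].to_numpy()
        out: list[tuple[str, slice]] = []
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], slice(start, i)))
                start = i
        return out


def is_autosome(chrom: str) -> bool:
    return chrom not in AUTOSOME_EXCLUDE
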