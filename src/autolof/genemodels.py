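"""Transcript models and coding-coordinate arithmetic.

A :class:`Transcript` stores exon and CDS intervals as 0-based half-open
genomic intervals sorted by genomic coordinate; transcript orientation (the
5'→3' direction of the mRNA) is genomic order for ``+`` strand genes and
reverse genomic order for ``-`` strand genes. CDS lengths are always a
multiple of three: the models represent complete open reading frames from
ATG through the stop codon.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from Bio.Seq import Seq

from .core import DataError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Translate with the standard genetic code; '*' marks stops."""
    return str(Seq(cds).translate())


@dataclass(frozen=True)
class Transcript:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"bad strand {self.strand!r}")
        for segs in (self.exons, self.cds_segments):
            for i in range(1, len(segs)):
                if segs[i][0] < segs[i - 1][1]:
                    raise DataError(
                        f"{self.transcript_id}: intervals overlap or unsorted"
                    )
        if self.cds_length_bp % 3 != 0:
            raise DataError(
                f"{self.transcript_id}: CDS length {self.cds_length_bp} "
                "not divisible by 3"
            )

    @property
    def cds_length_bp(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (0-based half-open) of the transcript."""
        return (self.exons[0][0], self.exons[-1][1])

    @cached_property
    def _cds_starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.cds_segments])

    @cached_property
    def _cds_ends(self) -> np.ndarray:
        return np.array([e for _, e in self.cds_segments])

    @cached_property
    def _cds_cumlen(self) -> np.ndarray:
        lens = self._cds_ends - self._cds_starts
        return np.concatenate([[0], np.cumsum(lens)])

    def cds_offset_of(self, gpos0: int) -> int | None:
        """Transcript-orientation CDS offset of a genomic base, or None."""
        i = int(np.searchsorted(self._cds_starts, gpos0, side="right")) - 1
        if i < 0 or gpos0 >= self._cds_ends[i]:
            return None
        plus_offset = int(self._cds_cumlen[i] + (gpos0 - self._cds_starts[i]))
        if self.strand == "+":
            return plus_offset
        return self.cds_length_bp - 1 - plus_offset

    def genomic_pos_of_offset(self, offset: int) -> int:
        """Inverse of :meth:`cds_offset_of` (0-based genomic position)."""
        if not 0 <= offset < self.cds_length_bp:
            raise DataError(f"CDS offset {offset} out of range")
        plus_offset = offset if self.strand == "+" else self.cds_length_bp - 1 - offset
        i = int(np.searchsorted(self._cds_cumlen, plus_offset, side="right")) - 1
        return int(self._cds_starts[i] + (plus_offset - self._cds_cumlen[i]))

    def in_exon(self, gpos0: int) -> bool:
        return any(s <= gpos0 < e for s, e in self.exons)

    def overlaps(self, start0: int, end0: int) -> bool:
        s, e = self.span
        return start0 < e and end0 > s

    def cds_sequence(self, reference: dict[str, str]) -> str:
        chrom_seq = reference[self.chrom]
        seq = "".join(chrom_seq[s:e] for s, e in self.cds_segments)
        return seq if self.strand == "+" else revcomp(seq)


class GeneModelSet:
    """Indexed collection of transcripts with cached CDS sequences."""

    def __init__(self, transcripts: list[Transcript], reference: dict[str, str]):
        if not transcripts:
            raise DataError("empty gene model set")
        self.transcripts = list(transcripts)
        self.reference = reference
        self.by_id = {t.transcript_id: t for t in self.transcripts}
        self.by_gene: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            self.by_gene.setdefault(t.gene_id, []).append(t)
        self._by_chrom: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda t: t.span)
        self._cds_cache: dict[str, str] = {}

    def overlapping(self, chrom: str, start0: int, end0: int) -> list[Transcript]:
        return [
            t for t in self._by_chrom.get(chrom, []) if t.overlaps(start0, end0)
        ]

    def cds_seq(self, transcript_id: str) -> str:
        if transcript_id not in self._cds_cache:
            t = self.by_id[transcript_id]
            self._cds_cache[transcript_id] = t.cds_sequence(self.reference)
        return self._cds_cache[transcript_id]

    def validate_orfs(self) -> None:
        """Check every transcript is a clean ORF (ATG .. single terminal stop)."""
        for t in self.transcripts:
            cds = self.cds_seq(t.transcript_id)
            prot = translate(cds)
            if not cds.startswith("ATG"):
                raise DataError(f"{t.transcript_id}: CDS does not start with ATG")
            if prot.count("*") != 1 or not prot.endswith("*"):
                raise DataError(
                    f"{t.transcript_id}: expected exactly one terminal stop"
                )


def reverse_complement_models(
    models: GeneModelSet, chrom_lengths: dict[str, int]
) -> GeneModelSet:
    """Mirror every chromosome (reverse-complement); used by symmetry tests."""
    new_ref = {c: revcomp(s) for c, s in models.reference.items()}
    flipped = []
    for t in models.transcripts:
        n = chrom_lengths[t.chrom]
        exons = tuple(sorted((n - e, n - s) for s, e in t.exons))
        cds = tuple(sorted((n - e, n - s) for s, e in t.cds_segments))
        flipped.append(
            Transcript(
                gene_id=t.gene_id,
                transcript_id=t.transcript_id,
                chrom=t.chrom,
                strand="-" if t.strand == "+" else "+",
                exons=exons,
                cds_segments=cds,
            )
        )
    return GeneModelSet(flipped, new_ref)
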