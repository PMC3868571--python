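"""Run-of-homozygosity (ROH) detection and genome-coverage summaries.

The caller is a deterministic maximal-run scan: per sample and chromosome,
missing calls and inter-SNP gaps longer than ``max_gap_bp`` split the site
sequence into segments, and within each segment homozygous runs are grown
left to right, tolerating up to ``max_het`` heterozygous calls per block
(blocks never start or end on a heterozygous site). With the default
``max_het=0`` this returns exactly the maximal homozygous runs. Block
boundaries are the positions of the outermost SNPs in the run.

Long ROHs (>= 2 Mb) proxy autozygosity (identity by descent); the default
100 kb floor keeps shorter, possibly identical-by-state runs available for
coverage curves at lower cutoffs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HET, HOM_ALT, HOM_REF, MISSING, DataError, GenotypeMatrix, RohBlock


@dataclass
class RohParams:
    min_length_bp: int = 100_000
    min_snps: int = 25
    max_het: int = 0
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("min_length_bp", "min_snps", "max_het", "max_gap_bp"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")


def _scan_sample(
    sample: str,
    chrom: str,
    positions: np.ndarray,
    codes: np.ndarray,
    params: RohParams,
) -> list[RohBlock]:
    blocks: list[RohBlock] = []
    n = len(positions)
    # split at missing calls and large gaps
    seg_start = 0
    boundaries = []
    for i in range(n):
        if codes[i] == MISSING:
            boundaries.append((seg_start, i))
            seg_start = i + 1
        elif i > seg_start and positions[i] - positions[i - 1] > params.max_gap_bp:
            boundaries.append((seg_start, i))
            seg_start = i
    boundaries.append((seg_start, n))

    hom = (codes == HOM_REF) | (codes == HOM_ALT)
    for a, b in boundaries:
        i = a
        while i < b:
            if not hom[i]:
                i += 1
                continue
            j = i
            hets = 0
            while j < b:
                if codes[j] == HET:
                    if hets + 1 > params.max_het:
                        break
                    hets += 1
                j += 1
            end = j - 1
            while codes[end] == HET:  # blocks end on a homozygous call
                hets -= 1
                end -= 1
            n_snps = end - i + 1
            length = int(positions[end] - positions[i] + 1)
            if n_snps >= params.min_snps and length >= params.min_length_bp:
                blocks.append(
                    RohBlock(
                        sample=sample,
                        chrom=chrom,
                        start_bp=int(positions[i]),
                        end_bp=int(positions[end]),
                        n_snps=n_snps,
                        n_het=hets,
                    )
                )
            i = max(j, end + 1)
    return blocks


def call_roh(genotypes: GenotypeMatrix, params: RohParams | None = None) -> list[RohBlock]:
    """Detect ROH blocks for every sample; deterministic, non-overlapping."""
    params = params or RohParams()
    blocks: list[RohBlock] = []
    slices = genotypes.chrom_slices()
    pos_all = genotypes.sites["pos"].to_numpy()
    for si, sample in enumerate(genotypes.samples):
        for chrom, sl in slices:
            blocks.extend(
                _scan_sample(
                    sample, chrom, pos_all[sl], genotypes.calls[sl, si], params
                )
            )
    blocks.sort(key=lambda b: (b.sample, b.chrom, b.start_bp))
    return blocks


def roh_coverage_fraction(
    blocks: list[RohBlock],
    min_length_bp: int,
    genome_size_bp: int,
    per_sample: bool = False,
    samples: list[str] | None = None,
):
    """Fraction of the genome covered by ROHs at or above a length cutoff.

    Per sample: summed qualifying block length / ``genome_size_bp``. The
    cohort value is the mean over samples; pass ``samples`` to include
    individuals with no blocks at all (they count as zero).
    """
    if genome_size_bp <= 0:
        raise DataError("genome_size_bp must be > 0")
    totals: dict[str, int] = {s: 0 for s in samples} if samples else {}
    for b in blocks:
        if b.length_bp >= min_length_bp:
            totals[b.sample] = totals.get(b.sample, 0) + b.length_bp
    fractions = {s: t / genome_size_bp for s, t in totals.items()}
    if per_sample:
        return fractions
    if not fractions:
        return 0.0
    return float(np.mean(list(fractions.values())))
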