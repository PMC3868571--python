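"""Shared fixtures: a session-scoped synthetic cohort and toy-transcript
builders used by the consequence-calling oracles."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from autolof.core import GenotypeMatrix
from autolof.genemodels import GeneModelSet, Transcript, revcomp
from autolof.simulate import SENSE_CODONS, CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default-scale synthetic cohort (77 individuals, 2 x 30 Mb)."""
    return simulate_cohort(CohortConfig(seed=7))


SMALL_CONFIG_KWARGS = dict(
    n_individuals=12,
    genome=(("chr1", 6_000_000), ("chr2", 6_000_000)),
    n_genes=16,
    site_counts={
        "synonymous": 80,
        "nonsynonymous": 80,
        "stop_gain": 50,
        "frameshift_indel": 50,
    },
    n_array_sites=600,
    n_rescue_pairs=1,
    n_same_codon_rescues=1,
    n_artifact_sites=1,
    n_ardg_genes=5,
)


@pytest.fixture()
def small_config():
    return CohortConfig(seed=11, **SMALL_CONFIG_KWARGS)


def make_toy_transcript(
    cds: str,
    strand: str = "+",
    exon_cuts: tuple[int, ...] = (),
    intron_len: int = 30,
    pad: int = 50,
    chrom: str = "chrT",
    rng: np.random.Generator | None = None,
):
    """Embed a CDS into a synthetic chromosome as a (possibly spliced) gene.

    ``exon_cuts`` are CDS offsets (transcript orientation, not necessarily
    codon-aligned) where introns are inserted. Returns (models, reference,
    gmap) where gmap[offset] is the 0-based genomic position of each CDS
    base in transcript orientation.
    """
    rng = rng or np.random.default_rng(0)
    cuts = [0, *sorted(exon_cuts), len(cds)]
    chunks = [cds[a:b] for a, b in zip(cuts, cuts[1:])]
    if strand == "-":
        chunks = [revcomp(c) for c in chunks[::-1]]
    background = "".join(rng.choice(list("ACGT"), size=pad + intron_len))
    seq_parts = []
    exons = []
    cur = pad
    seq_parts.append(background[:pad])
    for i, chunk in enumerate(chunks):
        exons.append((cur, cur + len(chunk)))
        seq_parts.append(chunk)
        cur += len(chunk)
        if i < len(chunks) - 1:
            intron = "".join(rng.choice(list("ACGT"), size=intron_len))
            seq_parts.append(intron)
            cur += intron_len
    seq_parts.append("".join(rng.choice(list("ACGT"), size=pad)))
    seq = "".join(seq_parts)
    t = Transcript(
        gene_id="gT",
        transcript_id="gT.t1",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_segments=tuple(exons),
    )
    models = GeneModelSet([t], {chrom: seq})
    if strand == "+":
        gmap = np.concatenate([np.arange(s, e) for s, e in exons])
    else:
        gmap = np.concatenate([np.arange(e - 1, s - 1, -1) for s, e in exons[::-1]])
    assert models.cds_seq("gT.t1") == cds
    return models, {chrom: seq}, gmap


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(SENSE_CODONS, size=n_codons - 2)
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
    return "ATG" + "".join(body) + stop


def matrix_from_calls(samples, rows, calls) -> GenotypeMatrix:
    """rows: list of (chrom, pos, ref, alt); calls: (n_sites, n_samples)."""
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(
        samples=list(samples), sites=sites, calls=np.asarray(calls, dtype=np.int8)
    )
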