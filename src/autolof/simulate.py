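"""Synthetic consanguineous cohort generator.

Produces a fully self-contained toy cohort - reference sequence, gene
models, variant sites, per-individual genotypes and ground truth - with
the statistical structure the downstream analysis assumes:

* per-individual autozygous ROH blocks whose mean genome fraction (at the
  2 Mb autozygosity cutoff) matches ``autozygosity_target``;
* class-ordered allele-frequency spectra (LoF rarer than nonsynonymous,
  nonsynonymous rarer than synonymous), drawn from per-class beta
  distributions;
* homozygous LoF placements enriched inside ROHs by a controlled factor
  ``1 + lof_roh_gain`` over the coverage-proportional baseline;
* planted rescue interactions and reference-artifact sites so the
  discovery filters have true positives to remove.

The generator is *not* a population-genetic simulator: ROH blocks are
planted directly rather than arising from pedigree inheritance, and all
distributional choices are pragmatic stand-ins (see docs/methods.md).
Everything is deterministic given ``seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    ConfigError,
    GenotypeMatrix,
    RohBlock,
)
from .genemodels import (
    STOP_CODONS,
    GeneModelSet,
    Transcript,
    revcomp,
    translate,
)

BASES = np.array(list("ACGT"))
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]
LOF_SITE_CLASSES = ("stop_gain", "frameshift_indel")
AUTOZYGOUS_CUTOFF_BP = 2_000_000


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the reference cohort: 77 individuals born to first
    cousin parents, a mean 7.7% of the genome in ROHs of 2 Mb or longer,
    allele-frequency medians ordered LoF < nonsynonymous < synonymous
    (about 4% / 6.5% / 9%), and homozygous-LoF placements 95% enriched
    inside the autozygome over the coverage-proportional expectation.
    Genome scale is a toy (2 chromosomes x 30 Mb, 60 genes) so the full
    pipeline runs in well under a minute.
    """

    n_individuals: int = 77
    genome: tuple[tuple[str, int], ...] = (("chr1", 30_000_000), ("chr2", 30_000_000))
    n_genes: int = 60
    transcripts_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.4}
    )
    site_counts: dict[str, int] = field(
        default_factory=lambda: {
            "synonymous": 600,
            "nonsynonymous": 600,
            "stop_gain": 300,
            "frameshift_indel": 300,
        }
    )
    n_array_sites: int = 6000  # ~10 kb spacing, SNP-chip-like density
    freq_spectra: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "synonymous": (1.6, 13.0),
            "nonsynonymous": (1.6, 18.6),
            "stop_gain": (1.6, 43.0),
            "frameshift_indel": (1.6, 43.0),
            "array": (2.0, 4.0),
        }
    )
    autozygosity_target: float = 0.077
    lof_roh_gain: float = 0.95
    het_rate_scale: float = 0.42
    n_rescue_pairs: int = 2
    n_same_codon_rescues: int = 2
    n_artifact_sites: int = 2
    n_ardg_genes: int = 15
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def genome_size_bp(self) -> int:
        return sum(length for _, length in self.genome)

    def validate(self) -> None:
        if self.n_individuals <= 0 or self.n_genes <= 0:
            raise ConfigError("counts must be > 0")
        if not 0.0 <= self.autozygosity_target < 1.0:
            raise ConfigError("autozygosity_target must be in [0, 1)")
        if self.lof_roh_gain < 0:
            raise ConfigError("lof_roh_gain must be >= 0")
        for name, length in self.genome:
            if length < 3_000_000:
                raise ConfigError(f"chromosome {name} shorter than 3 Mb")
        if abs(sum(self.transcripts_per_gene.values()) - 1.0) > 1e-9:
            raise ConfigError("transcripts_per_gene probabilities must sum to 1")
        for cls, (a, b) in self.freq_spectra.items():
            if a <= 0 or b <= 0:
                raise ConfigError(f"beta parameters for {cls} must be > 0")
        for cls, n in self.site_counts.items():
            if n <= 0:
                raise ConfigError(f"site count for {cls} must be > 0")
        n_coding = sum(self.site_counts.values())
        # rough capacity check: each gene hosts ~1 kb of CDS
        if n_coding > self.n_genes * 400:
            raise ConfigError("requested coding site density exceeds CDS capacity")
        if self.n_array_sites > self.genome_size_bp // 50:
            raise ConfigError("requested array site density exceeds genome length")
        if self.genome_size_bp < self.n_genes * 100_000:
            raise ConfigError("chromosomes too short to host requested genes")


@dataclass
class CohortTruth:
    """Ground truth for parameter-recovery tests."""

    planted_rohs: dict[str, list[RohBlock]]
    planted_knockouts: list[tuple[str, str, tuple]]
    class_of_site: dict[tuple, str]
    true_allele_freqs: dict[tuple, float]
    flagged_sites: dict[tuple, str]
    gene_of_site: dict[tuple, str | None]
    ardg_genes: list[str]


@dataclass
class SyntheticCohort:
    config: CohortConfig
    reference: dict[str, str]
    models: GeneModelSet
    matrix: GenotypeMatrix
    truth: CohortTruth
    ancestral: dict[tuple[str, int], str]

    @property
    def samples(self) -> list[str]:
        return self.matrix.samples


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


# ------------------------------------------------------------ reference


@dataclass
class _GeneInfo:
    gene_id: str
    chrom: str
    strand: str
    cds: str                      # coding-strand CDS of the full transcript
    gmap: np.ndarray              # CDS offset -> 0-based genomic position
    transcripts: list[Transcript]
    skipped_exon: tuple[int, int] | None  # genomic interval absent from t2


def generate_reference_and_genes(
    config: CohortConfig,
) -> tuple[dict[str, str], GeneModelSet]:
    """Random reference plus clean-ORF gene models (deterministic by seed)."""
    config.validate()
    rng = _rng(config, 0)
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    chrom_arrays = {
        name: base_codes[rng.integers(0, 4, size=length, dtype=np.uint8)]
        for name, length in config.genome
    }
    # evenly spaced slots across the concatenated usable genome
    margin = 1_000_000
    usable = [(name, margin, length - margin) for name, length in config.genome]
    total_usable = sum(e - s for _, s, e in usable)
    slot_w = total_usable // config.n_genes
    if slot_w < 30_000:
        raise ConfigError("chromosomes too short to host requested genes")

    tx_counts = sorted(config.transcripts_per_gene)
    tx_probs = [config.transcripts_per_gene[k] for k in tx_counts]

    genes: list[_GeneInfo] = []
    transcripts: list[Transcript] = []
    slot_origin = 0
    for gi in range(config.n_genes):
        gene_id = f"G{gi:03d}"
        # locate this gene's slot on the concatenated usable genome
        pos_concat = slot_origin
        chrom = None
        acc = 0
        for name, s, e in usable:
            if pos_concat < acc + (e - s):
                chrom = name
                chrom_slot_start = s + (pos_concat - acc)
                break
            acc += e - s
        slot_origin += slot_w

        n_exons = int(rng.integers(3, 6))
        exon_lens = 3 * rng.integers(20, 100, size=n_exons)
        intron_lens = rng.integers(500, 3000, size=n_exons - 1)
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        offset = int(rng.integers(0, max(1, slot_w - gene_len - 10_000)))
        gstart = chrom_slot_start + offset
        strand = "+" if rng.random() < 0.5 else "-"

        exons = []
        cur = gstart
        for i in range(n_exons):
            exons.append((cur, cur + int(exon_lens[i])))
            cur += int(exon_lens[i])
            if i < n_exons - 1:
                cur += int(intron_lens[i])
        cds_len = int(exon_lens.sum())
        n_codons = cds_len // 3
        body = rng.choice(SENSE_CODONS, size=n_codons - 2)
        stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
        cds = "ATG" + "".join(body) + stop

        # write CDS into the reference, exon by exon in transcript order
        tx_exons = exons if strand == "+" else exons[::-1]
        done = 0
        arr = chrom_arrays[chrom]
        for s, e in tx_exons:
            chunk = cds[done : done + (e - s)]
            done += e - s
            genomic = chunk if strand == "+" else revcomp(chunk)
            arr[s:e] = np.frombuffer(genomic.encode(), dtype=np.uint8)

        n_tx = int(rng.choice(tx_counts, p=tx_probs))
        t1 = Transcript(
            gene_id=gene_id,
            transcript_id=f"{gene_id}.t1",
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            cds_segments=tuple(exons),
        )
        tx_list = [t1]
        skipped = None
        if n_tx >= 2:
            skip_idx = int(rng.integers(1, n_exons - 1))  # internal exon
            skipped = exons[skip_idx]
            kept = tuple(e for i, e in enumerate(exons) if i != skip_idx)
            tx_list.append(
                Transcript(
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}.t2",
                    chrom=chrom,
                    strand=strand,
                    exons=kept,
                    cds_segments=kept,
                )
            )
        if strand == "+":
            gmap = np.concatenate([np.arange(s, e) for s, e in exons])
        else:
            gmap = np.concatenate(
                [np.arange(e - 1, s - 1, -1) for s, e in exons[::-1]]
            )
        genes.append(
            _GeneInfo(gene_id, chrom, strand, cds, gmap, tx_list, skipped)
        )
        transcripts.extend(tx_list)

    reference = {
        name: arr.tobytes().decode("ascii") for name, arr in chrom_arrays.items()
    }
    models = GeneModelSet(transcripts, reference)
    models.validate_orfs()
    models._gene_infos = genes  # internal handle for site planting
    return reference, models


# ------------------------------------------------------------ ROH planting


def plant_roh_structure(config: CohortConfig) -> dict[str, list[RohBlock]]:
    """Per-individual autozygous (>= 2 Mb) and short identical-by-state
    ROH blocks; mean long-block coverage targets ``autozygosity_target``."""
    config.validate()
    rng = _rng(config, 1)
    chrom_names = [name for name, _ in config.genome]
    chrom_lens = np.array([length for _, length in config.genome], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    G = config.genome_size_bp
    out: dict[str, list[RohBlock]] = {}
    for ind in range(config.n_individuals):
        sample = f"S{ind:03d}"
        placed: list[tuple[str, int, int]] = []

        def try_place(length: int) -> None:
            for _ in range(60):
                ci = int(rng.choice(len(chrom_names), p=chrom_p))
                cl = int(chrom_lens[ci])
                if length >= cl - 2:
                    continue
                start0 = int(rng.integers(0, cl - length))
                end0 = start0 + length
                name = chrom_names[ci]
                if all(
                    not (name == c and start0 < e and end0 > s)
                    for c, s, e in placed
                ):
                    placed.append((name, start0, end0))
                    return

        # long (candidate-autozygous) blocks: expectation-preserving draw
        if config.autozygosity_target > 0:
            c_i = rng.gamma(shape=4.0, scale=config.autozygosity_target / 4.0)
            c_i = min(c_i, 0.30)
            remaining = c_i * G
            max_block = min(18_000_000, int(min(chrom_lens) // 2))
            while remaining > 0:
                length = AUTOZYGOUS_CUTOFF_BP + rng.exponential(2_500_000)
                length = min(length, max_block)
                if length < remaining:
                    try_place(int(length))
                    remaining -= length
                elif remaining >= AUTOZYGOUS_CUTOFF_BP:
                    try_place(int(remaining))
                    remaining = 0
                else:
                    if rng.random() < remaining / AUTOZYGOUS_CUTOFF_BP:
                        try_place(AUTOZYGOUS_CUTOFF_BP)
                    remaining = 0

        # short blocks (long common haplotypes / identity by state)
        for _ in range(int(rng.poisson(12))):
            length = int(100_000 + rng.exponential(300_000))
            length = min(length, AUTOZYGOUS_CUTOFF_BP - 50_000)
            try_place(length)

        out[sample] = sorted(
            (
                RohBlock(sample=sample, chrom=c, start_bp=s + 1, end_bp=e)
                for c, s, e in placed
            ),
            key=lambda b: (b.chrom, b.start_bp),
        )
    return out


# ------------------------------------------------------------ genotypes


@dataclass
class _PlannedSite:
    chrom: str
    pos: int  # 1-based VCF position
    ref: str
    alt: str
    klass: str
    gene_id: str | None
    freq: float
    forced_hom: tuple[int, ...] | None = None  # sample indices, specials only
    flag: str | None = None


class _Reservations:
    """Minimum-spacing bookkeeping for planted site positions."""

    def __init__(self, pad: int = 6):
        self.pad = pad
        self.taken: set[tuple[str, int]] = set()

    def free(self, chrom: str, start0: int, end0: int, pad: int | None = None) -> bool:
        pad = self.pad if pad is None else pad
        return all(
            (chrom, p) not in self.taken for p in range(start0 - pad, end0 + pad)
        )

    def reserve(self, chrom: str, start0: int, end0: int) -> None:
        for p in range(start0 - self.pad, end0 + self.pad):
            self.taken.add((chrom, p))


def _snp_candidates(codon: str, want: str) -> list[tuple[int, str]]:
    """(within-codon position, alt base) choices giving the wanted class."""
    out = []
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if codon in STOP_CODONS:
                continue
            if mut in STOP_CODONS:
                klass = "stop_gain"
            elif translate(mut) == translate(codon):
                klass = "synonymous"
            else:
                klass = "nonsynonymous"
            if klass == want:
                out.append((i, b))
    return out


def _plant_snp(
    rng: np.random.Generator,
    gene: _GeneInfo,
    want: str,
    res: _Reservations,
    reference: dict[str, str],
) -> tuple[int, str, str, int] | None:
    """Returns (pos0, ref, alt, cds_offset) in genomic coordinates."""
    n_codons = len(gene.cds) // 3
    for _ in range(25):
        ci = int(rng.integers(1, n_codons - 1))
        codon = gene.cds[3 * ci : 3 * ci + 3]
        cands = _snp_candidates(codon, want)
        if not cands:
            continue
        within, alt_coding = cands[int(rng.integers(0, len(cands)))]
        offset = 3 * ci + within
        pos0 = int(gene.gmap[offset])
        if not res.free(gene.chrom, pos0, pos0 + 1):
            continue
        ref_base = reference[gene.chrom][pos0]
        alt_base = alt_coding if gene.strand == "+" else revcomp(alt_coding)
        res.reserve(gene.chrom, pos0, pos0 + 1)
        return pos0, ref_base, alt_base, offset
    return None


def _plant_frameshift(
    rng: np.random.Generator,
    gene: _GeneInfo,
    res: _Reservations,
    reference: dict[str, str],
) -> tuple[int, str, str] | None:
    """A frameshifting indel fully inside one exon; returns (pos0, ref, alt).

    Planted indels are either 1-bp insertions or 2-bp deletions: both have
    net length change congruent to +1 mod 3, so no pair of planted
    frameshifts can sum to 0 mod 3 and spuriously look like a
    complementary rescue. The rescue-pair planter is the only source of
    frame-restoring pairs.
    """
    t1 = gene.transcripts[0]
    seq = reference[gene.chrom]
    for _ in range(25):
        s, e = t1.exons[int(rng.integers(0, len(t1.exons)))]
        if e - s < 20:
            continue
        x = int(rng.integers(s + 5, e - 8))  # anchor; indel stays inside exon
        if not res.free(gene.chrom, x, x + 3):
            continue
        if rng.random() < 0.5:
            ref = seq[x : x + 3]  # 2-bp deletion
            alt = seq[x]
        else:
            ins = "".join(BASES[rng.integers(0, 4, size=1)])  # 1-bp insertion
            ref = seq[x]
            alt = seq[x] + ins
        res.reserve(gene.chrom, x, x + 3)
        return x, ref, alt
    return None


def generate_genotypes_and_vcf(
    config: CohortConfig,
    reference: dict[str, str],
    models: GeneModelSet,
    rohs: dict[str, list[RohBlock]],
) -> tuple[GenotypeMatrix, CohortTruth]:
    """Plant variant sites, draw genotypes, and assemble ground truth."""
    config.validate()
    rng = _rng(config, 2)
    genes: list[_GeneInfo] = models._gene_infos
    n = config.n_individuals
    samples = sorted(rohs)
    if len(samples) != n:
        raise ConfigError("rohs must cover every individual")
    res = _Reservations()
    planned: list[_PlannedSite] = []
    fs_positions: dict[str, list[int]] = {}  # gene -> frameshift anchors

    def draw_freq(klass: str) -> float:
        a, b = config.freq_spectra[klass]
        f = float(rng.beta(a, b))
        return min(max(f, 1.0 / (4 * n)), 0.85)

    # --- coding sites per class
    for klass, count in config.site_counts.items():
        made = 0
        attempts = 0
        while made < count:
            attempts += 1
            if attempts > 80 * count:
                raise ConfigError(
                    f"could not place {count} {klass} sites; genome too dense"
                )
            gene = genes[int(rng.integers(0, len(genes)))]
            if klass == "frameshift_indel":
                hit = _plant_frameshift(rng, gene, res, reference)
                if hit is None:
                    continue
                pos0, ref, alt = hit
                fs_positions.setdefault(gene.gene_id, []).append(pos0)
            else:
                hit = _plant_snp(rng, gene, klass, res, reference)
                if hit is None:
                    continue
                pos0, ref, alt, _ = hit
            planned.append(
                _PlannedSite(
                    gene.chrom, pos0 + 1, ref, alt, klass, gene.gene_id,
                    draw_freq(klass),
                )
            )
            made += 1

    # --- rescue pairs: complementary frameshifts in the same gene & carriers
    for _ in range(config.n_rescue_pairs):
        for _ in range(50):
            gene = genes[int(rng.integers(0, len(genes)))]
            t1 = gene.transcripts[0]
            wide = [(s, e) for s, e in t1.exons if e - s >= 120]
            if not wide:
                continue
            s, e = wide[int(rng.integers(0, len(wide)))]
            x1 = int(rng.integers(s + 5, e - 70))
            x2 = x1 + int(rng.integers(25, 60))
            if not (res.free(gene.chrom, x1, x1 + 3) and res.free(gene.chrom, x2, x2 + 3)):
                continue
            # keep frame-restoring pairs away from this gene's clean
            # frameshifts so they cannot recruit one into a false rescue
            if any(
                abs(p - x) <= 250
                for p in fs_positions.get(gene.gene_id, [])
                for x in (x1, x2)
            ):
                continue
            seq = reference[gene.chrom]
            ins = "".join(BASES[rng.integers(0, 4, size=1)])
            v1 = (x1, seq[x1], seq[x1] + ins)          # +1 insertion
            v2 = (x2, seq[x2 : x2 + 2], seq[x2])       # -1 deletion
            res.reserve(gene.chrom, x1, x1 + 3)
            res.reserve(gene.chrom, x2, x2 + 3)
            carriers = tuple(
                sorted(rng.choice(n, size=int(rng.integers(1, 3)), replace=False))
            )
            f = len(carriers) / n
            for pos0, ref, alt in (v1, v2):
                planned.append(
                    _PlannedSite(
                        gene.chrom, pos0 + 1, ref, alt, "frameshift_indel",
                        gene.gene_id, f, forced_hom=carriers, flag="rescued",
                    )
                )
            break

    # --- same-codon rescues: a stop-gain plus a second SNP in the codon
    for _ in range(config.n_same_codon_rescues):
        for _ in range(200):
            gene = genes[int(rng.integers(0, len(genes)))]
            n_codons = len(gene.cds) // 3
            ci = int(rng.integers(1, n_codons - 1))
            codon = gene.cds[3 * ci : 3 * ci + 3]
            stops = _snp_candidates(codon, "stop_gain")
            if not stops:
                continue
            i1, b1 = stops[int(rng.integers(0, len(stops)))]
            found = None
            for i2 in range(3):
                if i2 == i1:
                    continue
                for b2 in "ACGT":
                    if b2 == codon[i2]:
                        continue
                    joint = list(codon)
                    joint[i1] = b1
                    joint[i2] = b2
                    single = codon[:i2] + b2 + codon[i2 + 1 :]
                    if "".join(joint) not in STOP_CODONS and single not in STOP_CODONS:
                        found = (i2, b2, single)
                        break
                if found:
                    break
            if not found:
                continue
            i2, b2, single = found
            o1, o2 = 3 * ci + i1, 3 * ci + i2
            p1, p2 = int(gene.gmap[o1]), int(gene.gmap[o2])
            lo, hi = min(p1, p2), max(p1, p2)
            if not res.free(gene.chrom, lo, hi + 1):
                continue
            res.reserve(gene.chrom, lo, hi + 1)
            carriers = tuple(
                sorted(rng.choice(n, size=int(rng.integers(1, 3)), replace=False))
            )
            f = len(carriers) / n
            flip = (lambda b: b) if gene.strand == "+" else revcomp
            comp_class = (
                "synonymous" if translate(single) == translate(codon) else "nonsynonymous"
            )
            planned.append(
                _PlannedSite(
                    gene.chrom, p1 + 1, reference[gene.chrom][p1], flip(b1),
                    "stop_gain", gene.gene_id, f, forced_hom=carriers,
                    flag="rescued",
                )
            )
            planned.append(
                _PlannedSite(
                    gene.chrom, p2 + 1, reference[gene.chrom][p2], flip(b2),
                    comp_class, gene.gene_id, f, forced_hom=carriers,
                )
            )
            break

    # --- reference-artifact sites: near-fixed stop-gains, ancestral == alt
    ancestral: dict[tuple[str, int], str] = {}
    for _ in range(config.n_artifact_sites):
        for _ in range(200):
            gene = genes[int(rng.integers(0, len(genes)))]
            hit = _plant_snp(rng, gene, "stop_gain", res, reference)
            if hit is None:
                continue
            pos0, ref, alt, _ = hit
            k = int(np.ceil(n * float(rng.uniform(0.92, 0.98))))
            carriers = tuple(sorted(rng.choice(n, size=k, replace=False)))
            planned.append(
                _PlannedSite(
                    gene.chrom, pos0 + 1, ref, alt, "stop_gain", gene.gene_id,
                    k / n, forced_hom=carriers, flag="reference_artifact",
                )
            )
            ancestral[(gene.chrom, pos0 + 1)] = alt
            break

    # --- intergenic array sites (the SNP-chip layer for ROH calling)
    chrom_names = [name for name, _ in config.genome]
    chrom_lens = {name: length for name, length in config.genome}
    exonic: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for t in models.transcripts:
        exonic[t.chrom].extend(t.exons)
    total = config.genome_size_bp
    for name in chrom_names:
        want = int(round(config.n_array_sites * chrom_lens[name] / total))
        exon_starts = np.array(sorted(s for s, _ in exonic[name])) if exonic[name] else np.array([])
        exon_ends = np.array(sorted(e for _, e in sorted(exonic[name]))) if exonic[name] else np.array([])
        made = 0
        attempts = 0
        while made < want and attempts < 50 * want:
            attempts += 1
            pos0 = int(rng.integers(100, chrom_lens[name] - 100))
            if exon_starts.size:
                i = int(np.searchsorted(exon_starts, pos0, side="right")) - 1
                if i >= 0 and pos0 < exon_ends[i]:
                    continue
            if not res.free(name, pos0, pos0 + 1, pad=2):
                continue
            res.reserve(name, pos0, pos0 + 1)
            ref = reference[name][pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            planned.append(
                _PlannedSite(name, pos0 + 1, ref, alt, "array", None,
                             draw_freq("array"))
            )
            made += 1

    # --- sort sites and build membership masks
    planned.sort(key=lambda s: (s.chrom, s.pos))
    n_sites = len(planned)
    site_pos = np.array([s.pos for s in planned])
    site_chrom = np.array([s.chrom for s in planned])

    in_any = np.zeros((n_sites, n), dtype=bool)
    in_auto = np.zeros((n_sites, n), dtype=bool)  # blocks >= 2 Mb
    for si_idx, sample in enumerate(samples):
        for chrom in chrom_names:
            mask = site_chrom == chrom
            if not mask.any():
                continue
            pos_here = site_pos[mask]
            for min_len, target in (
                (0, in_any),
                (AUTOZYGOUS_CUTOFF_BP, in_auto),
            ):
                blocks = [
                    b
                    for b in rohs[sample]
                    if b.chrom == chrom and b.length_bp >= min_len
                ]
                if not blocks:
                    continue
                starts = np.array([b.start_bp for b in blocks])
                ends = np.array([b.end_bp for b in blocks])
                idx = np.searchsorted(starts, pos_here, side="right") - 1
                ok = (idx >= 0) & (pos_here <= ends[np.clip(idx, 0, None)])
                target[np.flatnonzero(mask)[ok], si_idx] = True

    # --- draw genotypes site by site
    g = config.lof_roh_gain
    # genome-wide mean autozygous coverage: the baseline the enrichment
    # statistic divides by, so the planted inside-probability targets
    # t = (1+g) * c_bar exactly
    G = config.genome_size_bp
    c_bar = float(
        np.mean(
            [
                sum(
                    b.length_bp
                    for b in rohs[s]
                    if b.length_bp >= AUTOZYGOUS_CUTOFF_BP
                )
                / G
                for s in samples
            ]
        )
    )
    t_inside = min((1 + g) * c_bar, 0.95)
    calls = np.full((n_sites, n), HOM_REF, dtype=np.int8)
    truth_knockouts: list[tuple[str, str, tuple]] = []
    class_of_site: dict[tuple, str] = {}
    true_freqs: dict[tuple, float] = {}
    flagged: dict[tuple, str] = {}
    gene_of_site: dict[tuple, str | None] = {}

    for i, site in enumerate(planned):
        key = (site.chrom, site.pos, site.ref, site.alt)
        class_of_site[key] = site.klass
        true_freqs[key] = site.freq
        gene_of_site[key] = site.gene_id
        if site.flag:
            flagged[key] = site.flag
        f = site.freq
        if site.forced_hom is not None:
            calls[i, list(site.forced_hom)] = HOM_ALT
            if site.flag is None and site.klass in LOF_SITE_CLASSES:
                for si_idx in site.forced_hom:
                    truth_knockouts.append(
                        (samples[si_idx], site.gene_id, key)
                    )
            continue
        if site.klass in LOF_SITE_CLASSES:
            z = in_auto[i]
            c = float(z.mean())
            if c <= 0 or c >= 1:
                q_in = q_out = f
            else:
                # carrier probability split so that E[carrier] = f and the
                # expected inside-fraction among carriers is t_inside
                q_in = min(1.0, f * t_inside / c)
                q_out = f * (1 - t_inside) / (1 - c)
            q = np.where(z, q_in, q_out)
            hom = rng.random(n) < q
            calls[i, hom] = HOM_ALT
            het_ok = ~hom & ~in_any[i]
            het = het_ok & (rng.random(n) < config.het_rate_scale * f)
            calls[i, het] = HET
            for si_idx in np.flatnonzero(hom):
                truth_knockouts.append((samples[si_idx], site.gene_id, key))
        else:
            u = rng.random(n)
            inside = in_any[i]
            hom = np.where(inside, u < f, u < f * f)
            het = ~inside & ~hom & (u < f * f + 2 * f * (1 - f))
            calls[i, hom] = HOM_ALT
            calls[i, het] = HET
        if config.missing_rate > 0:
            miss = ~in_any[i] & (rng.random(n) < config.missing_rate)
            calls[i, miss] = MISSING

    sites = pd.DataFrame(
        {
            "chrom": [s.chrom for s in planned],
            "pos": [s.pos for s in planned],
            "ref": [s.ref for s in planned],
            "alt": [s.alt for s in planned],
            "site_class": [s.klass for s in planned],
        }
    )
    matrix = GenotypeMatrix(samples=samples, sites=sites, calls=calls)

    ardg = sorted(
        str(gid)
        for gid in rng.choice(
            [g_.gene_id for g_ in genes], size=config.n_ardg_genes, replace=False
        )
    )
    # non-artifact sites carry the reference allele as ancestral
    for s in planned:
        ancestral.setdefault((s.chrom, s.pos), s.ref[0])

    truth = CohortTruth(
        planted_rohs=rohs,
        planted_knockouts=truth_knockouts,
        class_of_site=class_of_site,
        true_allele_freqs=true_freqs,
        flagged_sites=flagged,
        gene_of_site=gene_of_site,
        ardg_genes=ardg,
    )
    return matrix, truth


# ------------------------------------------------------------ top level


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    config = config or CohortConfig()
    reference, models = generate_reference_and_genes(config)
    rohs = plant_roh_structure(config)
    matrix, truth = generate_genotypes_and_vcf(config, reference, models, rohs)
    # ancestral alleles: alt at artifact sites, ref elsewhere
    ancestral: dict[tuple[str, int], str] = {}
    for key, flag in truth.flagged_sites.items():
        if flag == "reference_artifact":
            ancestral[(key[0], key[1])] = key[3]
    for key in truth.class_of_site:
        ancestral.setdefault((key[0], key[1]), key[2][0])
    return SyntheticCohort(
        config=config,
        reference=reference,
        models=models,
        matrix=matrix,
        truth=truth,
        ancestral=ancestral,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Persist the cohort as FASTA/GFF3/VCF/TSV files; returns the paths."""
    from pathlib import Path

    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = dict(cohort.config.genome)
    paths = {
        "fasta": str(out / "reference.fa"),
        "gff3": str(out / "genes.gff3"),
        "vcf": str(out / "cohort.vcf"),
        "array_vcf": str(out / "array.vcf"),
        "rohs_true": str(out / "truth_rohs.tsv"),
        "sites_true": str(out / "truth_sites.tsv"),
        "knockouts_true": str(out / "truth_knockouts.tsv"),
        "ardg": str(out / "ardg_genes.tsv"),
        "ancestral": str(out / "ancestral.tsv"),
    }
    io.write_fasta(cohort.reference, paths["fasta"])
    io.write_gff3(cohort.models.transcripts, paths["gff3"])
    io.write_vcf(cohort.matrix, paths["vcf"], contigs)
    array_rows = cohort.matrix.sites["site_class"] == "array"
    array_matrix = GenotypeMatrix(
        samples=cohort.matrix.samples,
        sites=cohort.matrix.sites[array_rows].reset_index(drop=True),
        calls=cohort.matrix.calls[array_rows.to_numpy()],
    )
    io.write_vcf(array_matrix, paths["array_vcf"], contigs)
    io.write_roh_tsv(
        [b for blocks in cohort.truth.planted_rohs.values() for b in blocks],
        paths["rohs_true"],
    )
    with open(paths["sites_true"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tclass\ttrue_freq\tflag\tgene\n")
        for key in sorted(cohort.truth.class_of_site):
            chrom, pos, ref, alt = key
            fh.write(
                f"{chrom}\t{pos}\t{ref}\t{alt}\t"
                f"{cohort.truth.class_of_site[key]}\t"
                f"{cohort.truth.true_allele_freqs[key]:.6f}\t"
                f"{cohort.truth.flagged_sites.get(key, '')}\t"
                f"{cohort.truth.gene_of_site[key] or ''}\n"
            )
    with open(paths["knockouts_true"], "w") as fh:
        fh.write("sample\tgene\tchrom\tpos\tref\talt\n")
        for sample, gene, key in sorted(cohort.truth.planted_knockouts):
            fh.write(f"{sample}\t{gene}\t{key[0]}\t{key[1]}\t{key[2]}\t{key[3]}\n")
    with open(paths["ardg"], "w") as fh:
        fh.write("gene\n")
        for gid in cohort.truth.ardg_genes:
            fh.write(f"{gid}\n")
    io.write_ancestral_tsv(cohort.ancestral, paths["ancestral"])
    return paths
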