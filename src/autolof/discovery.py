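"""Variant consequence calling and homozygous loss-of-function discovery.

The LoF definition is deliberately strict: a stop-gain SNP or a
frameshifting (length change not divisible by three) indel in a protein
coding gene. Splice-site variants, in-frame indels and missense changes are
never counted as LoF. Candidates are further screened for *rescue
interactions* (a nearby complementary frameshift restoring the reading
frame, or a second substitution in the same codon abolishing the gained
stop) and for reference-genome artifact signatures (an alternate allele
that is near-fixed in the cohort and matches the ancestral allele, which
suggests an error in the reference rather than a real knockout).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    HET,
    HOM_ALT,
    MISSING,
    DataError,
    GenotypeMatrix,
    VariantRecord,
    is_autosome,
)
from .genemodels import STOP_CODONS, GeneModelSet, Transcript, revcomp, translate

LOF_CLASSES = frozenset({"stop_gain", "frameshift_indel"})

FLAG_RESCUED_COMPLEMENTARY = "rescued_complementary_indel"
FLAG_RESCUED_SAME_CODON = "rescued_same_codon"
FLAG_REFERENCE_ARTIFACT = "reference_artifact"
FLAG_HIGH_FREQUENCY = "high_frequency"


class ReferenceMismatchError(DataError):
    """VCF REF allele disagrees with the reference sequence."""


@dataclass
class ConsequenceCall:
    variant: VariantRecord
    transcript_id: str
    gene_id: str
    klass: str
    cds_offset_bp: int | None = None


@dataclass
class LofCall:
    variant: VariantRecord
    gene_id: str
    klass: str
    carriers_hom: tuple[str, ...]
    carriers_het: tuple[str, ...]
    affects_all_transcripts: bool
    pos_in_cds: float
    transcript_id: str
    flags: frozenset[str] = frozenset()
    score: int | None = None
    hom_freq: float = 0.0
    allele_freq: float = 0.0


def _trim_shared_prefix(ref: str, alt: str) -> tuple[int, str, str]:
    """Strip the VCF anchor / shared prefix; returns (offset, del_seq, ins_seq)."""
    k = 0
    while k < len(ref) and k < len(alt) and ref[k] == alt[k]:
        k += 1
    return k, ref[k:], alt[k:]


def _overlap_len(start0: int, end0: int, segments) -> int:
    return sum(max(0, min(end0, e) - max(start0, s)) for s, e in segments)


def _classify_snp(
    v: VariantRecord, t: Transcript, models: GeneModelSet, g0: int, alt_base: str
) -> ConsequenceCall:
    offset = t.cds_offset_of(g0)
    if offset is None:
        return ConsequenceCall(v, t.transcript_id, t.gene_id, "noncoding")
    cds = models.cds_seq(t.transcript_id)
    coding_alt = alt_base if t.strand == "+" else revcomp(alt_base)
    ci, within = divmod(offset, 3)
    codon = cds[3 * ci : 3 * ci + 3]
    mutant = codon[:within] + coding_alt + codon[within + 1 :]
    if codon in STOP_CODONS:
        klass = "stop_loss" if mutant not in STOP_CODONS else "synonymous"
    elif mutant in STOP_CODONS:
        klass = "stop_gain"
    elif translate(codon) == translate(mutant):
        klass = "synonymous"
    else:
        klass = "nonsynonymous"
    return ConsequenceCall(v, t.transcript_id, t.gene_id, klass, offset)


def _classify_indel(
    v: VariantRecord,
    t: Transcript,
    g0: int,
    del_seq: str,
    ins_seq: str,
) -> ConsequenceCall:
    del_in_cds = _overlap_len(g0, g0 + len(del_seq), t.cds_segments)
    if del_seq:
        touches = del_in_cds > 0
        ins_in_cds = len(ins_seq) if del_in_cds > 0 else 0
    else:
        # pure insertion: counts only when the insertion point falls between
        # two CDS bases of the same segment
        touches = any(s < g0 < e for s, e in t.cds_segments)
        ins_in_cds = len(ins_seq) if touches else 0
    if not touches:
        return ConsequenceCall(v, t.transcript_id, t.gene_id, "noncoding")
    net = ins_in_cds - del_in_cds
    klass = "frameshift_indel" if net % 3 != 0 else "inframe_indel"
    # first affected CDS base in transcript orientation
    if del_seq:
        hits = [
            p
            for p in range(g0, g0 + len(del_seq))
            if t.cds_offset_of(p) is not None
        ]
        anchor = min(hits) if t.strand == "+" else max(hits)
        offset = t.cds_offset_of(anchor)
    else:
        anchor = g0 if t.strand == "+" else g0 - 1
        offset = t.cds_offset_of(anchor)
    return ConsequenceCall(v, t.transcript_id, t.gene_id, klass, offset)


def classify_variant(
    v: VariantRecord, models: GeneModelSet, reference: dict[str, str]
) -> list[ConsequenceCall]:
    """One consequence call per transcript overlapping the variant.

    Raises :class:`ReferenceMismatchError` when the VCF REF allele does not
    match the reference sequence (caller reports and skips the variant).
    """
    chrom_seq = reference[v.chrom]
    start0 = v.pos - 1
    if chrom_seq[start0 : start0 + len(v.ref)] != v.ref:
        raise ReferenceMismatchError(
            f"REF mismatch at {v.chrom}:{v.pos} "
            f"(vcf={v.ref!r}, fasta={chrom_seq[start0:start0 + len(v.ref)]!r})"
        )
    k, del_seq, ins_seq = _trim_shared_prefix(v.ref, v.alt)
    g0 = start0 + k
    end0 = max(g0 + len(del_seq), g0 + 1)
    calls = []
    for t in models.overlapping(v.chrom, start0, start0 + max(len(v.ref), 1)):
        if v.is_snp:
            calls.append(_classify_snp(v, t, models, g0, ins_seq))
        elif len(del_seq) == len(ins_seq):  # MNP-style substitution
            # classify base-by-base; report the strongest effect
            sub = [
                _classify_snp(v, t, models, g0 + i, ins_seq[i])
                for i in range(len(del_seq))
            ]
            order = [
                "stop_gain", "stop_loss", "nonsynonymous", "synonymous", "noncoding"
            ]
            best = min(sub, key=lambda c: order.index(c.klass))
            calls.append(
                ConsequenceCall(
                    v, t.transcript_id, t.gene_id, best.klass, best.cds_offset_bp
                )
            )
        else:
            calls.append(_classify_indel(v, t, g0, del_seq, ins_seq))
    return calls


# ------------------------------------------------------------- rescues


def detect_rescue_interactions(
    calls: list[ConsequenceCall],
    models: GeneModelSet,
    rescue_window_bp: int = 200,
) -> dict[tuple, set[str]]:
    """Flag rescue interactions among one gene's calls in one individual.

    ``calls`` must all belong to the same gene and the same (homozygous)
    carrier; phase is ignored. Returns variant key -> flag set.
    """
    flags: dict[tuple, set[str]] = {c.variant.key: set() for c in calls}

    frameshifts = [c for c in calls if c.klass == "frameshift_indel"]
    for i in range(len(frameshifts)):
        for j in range(i + 1, len(frameshifts)):
            a, b = frameshifts[i], frameshifts[j]
            if a.transcript_id != b.transcript_id:
                continue
            if abs(a.variant.pos - b.variant.pos) > rescue_window_bp:
                continue
            if (a.variant.net_length_change + b.variant.net_length_change) % 3 == 0:
                flags[a.variant.key].add(FLAG_RESCUED_COMPLEMENTARY)
                flags[b.variant.key].add(FLAG_RESCUED_COMPLEMENTARY)

    snvs = [c for c in calls if c.variant.is_snp and c.cds_offset_bp is not None]
    for sg in [c for c in snvs if c.klass == "stop_gain"]:
        t = models.by_id[sg.transcript_id]
        cds = models.cds_seq(sg.transcript_id)
        ci = sg.cds_offset_bp // 3
        codon = list(cds[3 * ci : 3 * ci + 3])
        partners = [
            c
            for c in snvs
            if c.transcript_id == sg.transcript_id
            and c.variant.key != sg.variant.key
            and c.cds_offset_bp // 3 == ci
        ]
        if not partners:
            continue
        joint = codon[:]
        for c in [sg] + partners:
            base = c.variant.alt if t.strand == "+" else revcomp(c.variant.alt)
            joint[c.cds_offset_bp % 3] = base
        if "".join(joint) not in STOP_CODONS:
            flags[sg.variant.key].add(FLAG_RESCUED_SAME_CODON)
    return flags


# ------------------------------------------------------------- artifacts


def allele_frequency(v: VariantRecord) -> tuple[float, float, float]:
    """(allele_freq, hom_freq, het_freq) from the per-sample genotypes."""
    if v.genotypes is None:
        raise DataError("variant has no genotypes")
    g = np.asarray(v.genotypes)
    called = g != MISSING
    n = int(called.sum())
    if n == 0:
        raise DataError(f"all genotypes missing at {v.chrom}:{v.pos}")
    n_hom = int((g == HOM_ALT).sum())
    n_het = int((g == HET).sum())
    return ((n_het + 2 * n_hom) / (2 * n), n_hom / n, n_het / n)


def flag_reference_artifacts(
    v: VariantRecord, artifact_threshold: float = 0.90
) -> set[str]:
    """Signatures of a reference-genome error masquerading as an LoF.

    When the alternate allele is homozygous in nearly everyone and the
    ancestral allele is unknown or equals the alternate, the "LoF" most
    likely recovers the ancestral state and the reference carries the
    derived (broken) allele.
    """
    _, hom_freq, _ = allele_frequency(v)
    flags: set[str] = set()
    if hom_freq >= artifact_threshold:
        flags.add(FLAG_HIGH_FREQUENCY)
        if v.ancestral is None or v.ancestral == v.alt:
            flags.add(FLAG_REFERENCE_ARTIFACT)
    return flags


# ------------------------------------------------------------- table


def _pick_reference_transcript(
    models: GeneModelSet, lof_calls: list[ConsequenceCall]
) -> ConsequenceCall:
    """The call on the longest affected transcript (ties: lexicographic id)."""
    return max(
        lof_calls,
        key=lambda c: (models.by_id[c.transcript_id].cds_length_bp, c.transcript_id),
    )


def build_homozygous_lof_table(
    matrix: GenotypeMatrix,
    models: GeneModelSet,
    reference: dict[str, str],
    autosomes_only: bool = False,
    ancestral: dict[tuple[str, int], str] | None = None,
    rescue_window_bp: int = 200,
    artifact_threshold: float = 0.90,
    report_skipped: list | None = None,
    stage_counts: dict | None = None,
) -> list[LofCall]:
    """Assemble the confirmed homozygous-LoF candidate table.

    Keeps variants that are homozygous alternate in at least one sample,
    LoF on at least one transcript, and not flagged as rescued or as a
    reference artifact. Deterministic order: (chrom, pos, alt).
    """
    ancestral = ancestral or {}
    classified: dict[tuple, list[ConsequenceCall]] = {}
    variants: dict[tuple, VariantRecord] = {}
    for i in range(matrix.n_sites):
        v = matrix.variant(i)
        v.ancestral = ancestral.get((v.chrom, v.pos))
        try:
            calls = classify_variant(v, models, reference)
        except ReferenceMismatchError as exc:
            if report_skipped is not None:
                report_skipped.append(str(exc))
            continue
        variants[v.key] = v
        classified[v.key] = calls

    # per (gene, sample) map of that sample's homozygous calls for rescues
    by_gene_sample: dict[tuple[str, str], list[ConsequenceCall]] = {}
    for key, calls in classified.items():
        v = variants[key]
        hom_samples = [
            matrix.samples[si] for si in np.flatnonzero(v.genotypes == HOM_ALT)
        ]
        for c in calls:
            if c.klass in ("noncoding",):
                continue
            for s in hom_samples:
                by_gene_sample.setdefault((c.gene_id, s), []).append(c)

    rescue_flags: dict[tuple, set[str]] = {}
    for (_, _), calls in by_gene_sample.items():
        if len(calls) < 2:
            continue
        for key, fl in detect_rescue_interactions(
            calls, models, rescue_window_bp
        ).items():
            if fl:
                rescue_flags.setdefault(key, set()).update(fl)

    table: list[LofCall] = []
    n_candidates = 0
    for key in sorted(classified, key=lambda k: (k[0], k[1], k[3])):
        v = variants[key]
        if autosomes_only and not is_autosome(v.chrom):
            continue
        calls = classified[key]
        lof_calls = [c for c in calls if c.klass in LOF_CLASSES]
        if not lof_calls:
            continue
        hom_idx = np.flatnonzero(v.genotypes == HOM_ALT)
        if len(hom_idx) == 0:
            continue
        n_candidates += 1
        flags = set(rescue_flags.get(key, set()))
        flags |= flag_reference_artifacts(v, artifact_threshold)
        if flags & {
            FLAG_RESCUED_COMPLEMENTARY,
            FLAG_RESCUED_SAME_CODON,
            FLAG_REFERENCE_ARTIFACT,
        }:
            continue
        ref_call = _pick_reference_transcript(models, lof_calls)
        gene_id = ref_call.gene_id
        gene_ts = {t.transcript_id for t in models.by_gene[gene_id]}
        affected = {c.transcript_id for c in lof_calls if c.gene_id == gene_id}
        t = models.by_id[ref_call.transcript_id]
        allele_f, hom_f, _ = allele_frequency(v)
        table.append(
            LofCall(
                variant=v,
                gene_id=gene_id,
                klass=ref_call.klass,
                carriers_hom=tuple(matrix.samples[i] for i in hom_idx),
                carriers_het=tuple(
                    matrix.samples[i] for i in np.flatnonzero(v.genotypes == HET)
                ),
                affects_all_transcripts=affected == gene_ts,
                pos_in_cds=pos_in_cds_fraction(
                    ref_call.cds_offset_bp, t.cds_length_bp
                ),
                transcript_id=ref_call.transcript_id,
                flags=frozenset(flags),
                hom_freq=hom_f,
                allele_freq=allele_f,
            )
        )
    if stage_counts is not None:
        stage_counts["variants_total"] = matrix.n_sites
        stage_counts["variants_classified"] = len(classified)
        stage_counts["hom_lof_candidates"] = n_candidates
        stage_counts["confirmed_lof"] = len(table)
    return table


def heterozygous_lof_carriers(
    matrix: GenotypeMatrix,
    models: GeneModelSet,
    reference: dict[str, str],
    autosomes_only: bool = False,
) -> pd.DataFrame:
    """(gene, sample) pairs with a heterozygous LoF call; for carrier burden."""
    rows = []
    for i in range(matrix.n_sites):
        v = matrix.variant(i)
        if autosomes_only and not is_autosome(v.chrom):
            continue
        try:
            calls = classify_variant(v, models, reference)
        except ReferenceMismatchError:
            continue
        genes = {c.gene_id for c in calls if c.klass in LOF_CLASSES}
        if not genes:
            continue
        for si in np.flatnonzero(v.genotypes == HET):
            for gene in sorted(genes):
                rows.append(
                    (gene, matrix.samples[si], v.chrom, v.pos, v.ref, v.alt)
                )
    return pd.DataFrame(
        rows, columns=["gene", "sample", "chrom", "pos", "ref", "alt"]
    )


def lof_table_to_frame(table: list[LofCall]) -> pd.DataFrame:
    """Confirmed-variant table mirroring the standard report columns."""
    rows = []
    for c in table:
        rows.append(
            {
                "Gene": c.gene_id,
                "Chr": c.variant.chrom,
                "Location": c.variant.pos,
                "Score": c.score if c.score is not None else "",
                "Ref Allele": c.variant.ref,
                "Alt Allele": c.variant.alt,
                "Annotation": c.klass,
                "NGS Seen in": len(c.carriers_hom),
                "Observed Freq": round(c.hom_freq, 6),
                "Pos in CDS": round(c.pos_in_cds, 6),
                "On All Transcripts": c.affects_all_transcripts,
                "Flags": ";".join(sorted(c.flags)),
                "Carriers": ",".join(c.carriers_hom),
            }
        )
    return pd.DataFrame(rows)


def pos_in_cds_fraction(cds_offset_bp: int, cds_length_bp: int) -> float:
    """Relative location of the first affected base along the CDS, in [0, 1)."""
    if cds_length_bp <= 0 or cds_length_bp % 3 != 0:
        raise DataError(f"bad CDS length {cds_length_bp}")
    if not 0 <= cds_offset_bp < cds_length_bp:
        raise DataError(
            f"CDS offset {cds_offset_bp} outside [0, {cds_length_bp})"
        )
    return cds_offset_bp / cds_length_bp
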