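"""Consequence calling, rescue/artifact filters, and the homozygous-LoF table."""
from __future__ import annotations

import numpy as np
import pytest

from autolof.core import HET, HOM_ALT, HOM_REF, DataError, VariantRecord
from autolof.discovery import (
    FLAG_HIGH_FREQUENCY,
    FLAG_REFERENCE_ARTIFACT,
    FLAG_RESCUED_COMPLEMENTARY,
    FLAG_RESCUED_SAME_CODON,
    ReferenceMismatchError,
    allele_frequency,
    build_homozygous_lof_table,
    classify_variant,
    detect_rescue_interactions,
    flag_reference_artifacts,
    pos_in_cds_fraction,
)
from autolof.genemodels import (
    STOP_CODONS,
    revcomp,
    reverse_complement_models,
    translate,
)

from conftest import make_toy_transcript, matrix_from_calls, random_cds

#                 M  Q(CAA) G(GGA) L  K  stop
CDS = "ATG" + "CAA" + "GGA" + "CTT" + "AAA" + "TAA"


def _variant_at_offset(models, gmap, offset, coding_alt, strand):
    t = models.transcripts[0]
    pos0 = int(gmap[offset])
    ref = models.reference[t.chrom][pos0]
    alt = coding_alt if strand == "+" else revcomp(coding_alt)
    return VariantRecord(chrom=t.chrom, pos=pos0 + 1, ref=ref, alt=alt)


@pytest.mark.parametrize("strand", ["+", "-"])
@pytest.mark.parametrize(
    "offset,alt,expected",
    [
        (3, "T", "stop_gain"),       # CAA -> TAA
        (8, "G", "synonymous"),      # GGA -> GGG (both Gly)
        (4, "T", "nonsynonymous"),   # CAA -> CTA (Gln -> Leu)
    ],
)
def test_classify_snp_examples(strand, offset, alt, expected):
    models, ref, gmap = make_toy_transcript(CDS, strand=strand)
    v = _variant_at_offset(models, gmap, offset, alt, strand)
    calls = classify_variant(v, models, ref)
    assert [c.klass for c in calls] == [expected]
    assert calls[0].cds_offset_bp == offset


@pytest.mark.parametrize("strand", ["+", "-"])
def test_classify_indels(strand):
    models, ref, gmap = make_toy_transcript(CDS, strand=strand)
    t = models.transcripts[0]
    chrom_seq = ref[t.chrom]
    s, e = t.exons[0]
    # 1-bp deletion inside CDS -> frameshift
    v = VariantRecord(
        chrom=t.chrom, pos=s + 4, ref=chrom_seq[s + 3 : s + 5], alt=chrom_seq[s + 3]
    )
    assert [c.klass for c in classify_variant(v, models, ref)] == ["frameshift_indel"]
    # 3-bp deletion inside CDS -> in-frame, not LoF
    v3 = VariantRecord(
        chrom=t.chrom, pos=s + 4, ref=chrom_seq[s + 3 : s + 7], alt=chrom_seq[s + 3]
    )
    assert [c.klass for c in classify_variant(v3, models, ref)] == ["inframe_indel"]
    # insertion in flanking sequence -> noncoding for an overlapping query
    v_out = VariantRecord(
        chrom=t.chrom, pos=e + 5, ref=chrom_seq[e + 4], alt=chrom_seq[e + 4] + "T"
    )
    calls = classify_variant(v_out, models, ref)
    assert all(c.klass == "noncoding" for c in calls)


def test_reference_mismatch_raises():
    models, ref, gmap = make_toy_transcript(CDS)
    v = VariantRecord(chrom="chrT", pos=int(gmap[3]) + 1, ref="N", alt="T")
    with pytest.raises(ReferenceMismatchError):
        classify_variant(v, models, ref)


def test_strand_symmetry_on_random_transcripts():
    """Mirroring the chromosome (reverse complement of reference, model and
    alleles) must leave every class label unchanged."""
    rng = np.random.default_rng(5)
    for _ in range(25):
        cds = random_cds(rng, int(rng.integers(10, 40)))
        cuts = sorted(
            int(x) for x in rng.choice(np.arange(4, len(cds) - 4), size=2, replace=False)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        models, ref, gmap = make_toy_transcript(cds, strand=strand, exon_cuts=tuple(cuts), rng=rng)
        n = len(ref["chrT"])
        mirrored = reverse_complement_models(models, {"chrT": n})
        for _ in range(8):
            offset = int(rng.integers(0, len(cds) - 3))
            base = str(rng.choice(list("ACGT")))
            if base == cds[offset]:
                continue
            v = _variant_at_offset(models, gmap, offset, base, strand)
            fwd = classify_variant(v, models, ref)
            v_rc = VariantRecord(
                chrom="chrT",
                pos=n - v.pos + 1,
                ref=revcomp(v.ref),
                alt=revcomp(v.alt),
            )
            rev = classify_variant(v_rc, mirrored, mirrored.reference)
            assert [c.klass for c in fwd] == [c.klass for c in rev]
            assert [c.cds_offset_bp for c in fwd] == [c.cds_offset_bp for c in rev]


def _retranslation_oracle(cds, offset, coding_alt):
    """Independent expectation for an SNV: rebuild the mutant CDS and
    translate it with the standard code."""
    ci = offset // 3
    codon = cds[3 * ci : 3 * ci + 3]
    mutant_cds = cds[:offset] + coding_alt + cds[offset + 1 :]
    mut_codon = mutant_cds[3 * ci : 3 * ci + 3]
    if codon in STOP_CODONS:
        return "synonymous" if mut_codon in STOP_CODONS else "stop_loss"
    if mut_codon in STOP_CODONS:
        return "stop_gain"
    if translate(mutant_cds) == translate(cds):
        return "synonymous"
    return "nonsynonymous"


def run_retranslation_oracle(n_transcripts, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n_transcripts):
        n_codons = int(rng.integers(8, 60))
        cds = random_cds(rng, n_codons)
        n_cuts = int(rng.integers(0, 3))
        cuts = tuple(
            sorted(
                int(x)
                for x in rng.choice(
                    np.arange(4, len(cds) - 4), size=n_cuts, replace=False
                )
            )
        )
        strand = "+" if rng.random() < 0.5 else "-"
        models, ref, gmap = make_toy_transcript(
            cds, strand=strand, exon_cuts=cuts, rng=rng
        )
        for _ in range(4):
            offset = int(rng.integers(0, len(cds)))
            base = str(rng.choice(list("ACGT")))
            if base == cds[offset]:
                continue
            v = _variant_at_offset(models, gmap, offset, base, strand)
            calls = classify_variant(v, models, ref)
            assert len(calls) == 1
            assert calls[0].klass == _retranslation_oracle(cds, offset, base)
            assert calls[0].cds_offset_bp == offset


def test_retranslation_oracle_small():
    run_retranslation_oracle(60, seed=17)


def test_rescue_complementary_indels():
    cds = random_cds(np.random.default_rng(2), 60)
    models, ref, gmap = make_toy_transcript(cds)
    t = models.transcripts[0]
    s, _ = t.exons[0]
    seq = ref["chrT"]
    x1, x2 = s + 10, s + 50  # 40 bp apart, window 200
    v_ins = VariantRecord(chrom="chrT", pos=x1 + 1, ref=seq[x1], alt=seq[x1] + "A")
    v_del = VariantRecord(chrom="chrT", pos=x2 + 1, ref=seq[x2 : x2 + 2], alt=seq[x2])
    calls = classify_variant(v_ins, models, ref) + classify_variant(v_del, models, ref)
    assert {c.klass for c in calls} == {"frameshift_indel"}
    flags = detect_rescue_interactions(calls, models, rescue_window_bp=200)
    assert flags[v_ins.key] == {FLAG_RESCUED_COMPLEMENTARY}
    assert flags[v_del.key] == {FLAG_RESCUED_COMPLEMENTARY}
    # outside the window: no rescue
    flags_narrow = detect_rescue_interactions(calls, models, rescue_window_bp=20)
    assert not flags_narrow[v_ins.key]


def test_rescue_same_codon():
    #                  M     Y(TAC)  L     K    stop
    cds = "ATG" + "TAC" + "CTT" + "AAA" + "TAA"
    models, ref, gmap = make_toy_transcript(cds)
    # TAC -> TAA (stop gain at codon position 3)
    sg = _variant_at_offset(models, gmap, 5, "A", "+")
    # second SNP at codon position 2: joint codon TCA -> not a stop: rescued
    partner = _variant_at_offset(models, gmap, 4, "C", "+")
    calls = classify_variant(sg, models, ref) + classify_variant(partner, models, ref)
    flags = detect_rescue_interactions(calls, models)
    assert FLAG_RESCUED_SAME_CODON in flags[sg.key]
    # joint codon still a stop (TAC -> TAA plus T->T no-op partner in next codon)
    other = _variant_at_offset(models, gmap, 7, "G", "+")  # different codon
    calls2 = classify_variant(sg, models, ref) + classify_variant(other, models, ref)
    flags2 = detect_rescue_interactions(calls2, models)
    assert not flags2[sg.key]


def test_same_codon_still_stop_is_not_rescued():
    #            M     C(TGC)...
    cds = "ATG" + "TGC" + "CTT" + "AAA" + "TAA"
    models, ref, gmap = make_toy_transcript(cds)
    # TGC -> TGA (stop). Partner at position 2: G->A gives joint TAA: still stop.
    sg = _variant_at_offset(models, gmap, 5, "A", "+")
    partner = _variant_at_offset(models, gmap, 4, "A", "+")
    calls = classify_variant(sg, models, ref) + classify_variant(partner, models, ref)
    flags = detect_rescue_interactions(calls, models)
    assert FLAG_RESCUED_SAME_CODON not in flags[sg.key]


@pytest.mark.parametrize(
    "n_hom,ancestral,expected",
    [
        (76, "alt", {FLAG_HIGH_FREQUENCY, FLAG_REFERENCE_ARTIFACT}),
        (3, "alt", set()),
        (75, "ref", {FLAG_HIGH_FREQUENCY}),
        (76, None, {FLAG_HIGH_FREQUENCY, FLAG_REFERENCE_ARTIFACT}),
    ],
)
def test_flag_reference_artifacts(n_hom, ancestral, expected):
    g = np.full(77, HOM_REF, dtype=np.int8)
    g[:n_hom] = HOM_ALT
    anc = {"alt": "T", "ref": "A", None: None}[ancestral]
    v = VariantRecord(chrom="chr1", pos=100, ref="A", alt="T", genotypes=g, ancestral=anc)
    assert flag_reference_artifacts(v) == expected


def test_allele_frequency_arithmetic():
    g = np.array([HOM_ALT] * 2 + [HOM_REF] * 8, dtype=np.int8)
    v = VariantRecord(chrom="c", pos=1, ref="A", alt="T", genotypes=g)
    assert allele_frequency(v) == pytest.approx((0.20, 0.20, 0.0))
    g0 = np.full(10, HOM_REF, dtype=np.int8)
    v0 = VariantRecord(chrom="c", pos=1, ref="A", alt="T", genotypes=g0)
    assert allele_frequency(v0) == (0.0, 0.0, 0.0)
    g77 = np.full(77, HOM_REF, dtype=np.int8)
    g77[:6] = HOM_ALT
    v77 = VariantRecord(chrom="c", pos=1, ref="A", alt="T", genotypes=g77)
    af, hom, het = allele_frequency(v77)
    assert hom == pytest.approx(6 / 77)


def test_allele_frequency_sample_order_invariance():
    rng = np.random.default_rng(1)
    g = rng.choice([HOM_REF, HET, HOM_ALT], size=50).astype(np.int8)
    v1 = VariantRecord(chrom="c", pos=1, ref="A", alt="T", genotypes=g)
    v2 = VariantRecord(chrom="c", pos=1, ref="A", alt="T", genotypes=rng.permutation(g))
    assert allele_frequency(v1) == allele_frequency(v2)


def test_pos_in_cds_fraction():
    assert pos_in_cds_fraction(0, 300) == 0.0
    assert pos_in_cds_fraction(150, 300) == 0.5
    # codon 55 of a 305-codon protein: near the start of the ORF
    assert pos_in_cds_fraction(162, 915) == pytest.approx(0.177, abs=1e-3)
    with pytest.raises(DataError):
        pos_in_cds_fraction(300, 300)


def test_hom_table_on_toy_cohort():
    models, ref, gmap = make_toy_transcript(CDS)
    sg = _variant_at_offset(models, gmap, 3, "T", "+")  # mid-CDS stop gain
    rows = [(sg.chrom, sg.pos, sg.ref, sg.alt)]
    calls = np.array([[HOM_ALT, HOM_REF, HET]], dtype=np.int8)
    matrix = matrix_from_calls(["S0", "S1", "S2"], rows, calls)
    table = build_homozygous_lof_table(matrix, models, ref)
    assert len(table) == 1
    call = table[0]
    assert call.klass == "stop_gain"
    assert call.carriers_hom == ("S0",)
    assert call.affects_all_transcripts is True
    assert not call.flags
    # het-only variant is excluded from the homozygous table
    het_only = np.array([[HET, HET, HOM_REF]], dtype=np.int8)
    m2 = matrix_from_calls(["S0", "S1", "S2"], rows, het_only)
    assert build_homozygous_lof_table(m2, models, ref) == []


def test_table_matches_planted_truth(cohort):
    """Discovery reproduces the generator's clean knockouts exactly:
    planted rescues and reference artifacts are filtered, nothing else."""
    table = build_homozygous_lof_table(
        cohort.matrix, cohort.models, cohort.reference, ancestral=cohort.ancestral
    )
    truth_keys = {key for (_, _, key) in cohort.truth.planted_knockouts}
    table_keys = {c.variant.key for c in table}
    assert table_keys == truth_keys
    flagged = set(cohort.truth.flagged_sites)
    assert not (table_keys & flagged)
    for c in table:
        assert not (
            c.flags
            & {FLAG_RESCUED_COMPLEMENTARY, FLAG_RESCUED_SAME_CODON, FLAG_REFERENCE_ARTIFACT}
        )
        assert c.carriers_hom
        assert 0.0 <= c.pos_in_cds < 1.0
    # carrier sets agree with the planted knockout list
    by_key = {}
    for sample, gene, key in cohort.truth.planted_knockouts:
        by_key.setdefault(key, set()).add(sample)
    for c in table:
        assert set(c.carriers_hom) == by_key[c.variant.key]


def test_class_roundtrip_against_truth(cohort):
    """Reclassifying emitted variants reproduces the generator's class
    labels on the transcripts that contain each site."""
    rng = np.random.default_rng(0)
    keys = sorted(cohort.truth.class_of_site)
    sites = cohort.matrix.sites
    lookup = {
        (c, p, r, a): i
        for i, (c, p, r, a) in enumerate(
            zip(sites["chrom"], sites["pos"], sites["ref"], sites["alt"])
        )
    }
    sample_idx = rng.choice(len(keys), size=400, replace=False)
    for ki in sample_idx:
        key = keys[ki]
        truth_class = cohort.truth.class_of_site[key]
        v = cohort.matrix.variant(lookup[key])
        calls = classify_variant(v, cohort.models, cohort.reference)
        classes = {c.klass for c in calls}
        if truth_class == "array":
            assert not classes or classes == {"noncoding"}
        else:
            assert truth_class in classes
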