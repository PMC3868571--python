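"""Enrichment, binomial bias, rank tests and carrier burden."""
from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from autolof.core import DataError, RohBlock, VariantRecord
from autolof.discovery import LofCall
from autolof.stats import (
    allele_autozygome_bias,
    carrier_burden,
    compare_frequency_distributions,
    enrichment_curve,
    enrichment_gain,
    exact_mann_whitney_p,
    lof_in_roh_fraction,
    mann_whitney_p,
    mann_whitney_u,
)

import pandas as pd


def _call(chrom, pos, carriers, gene="g1"):
    return LofCall(
        variant=VariantRecord(chrom=chrom, pos=pos, ref="A", alt="T"),
        gene_id=gene,
        klass="stop_gain",
        carriers_hom=tuple(carriers),
        carriers_het=(),
        affects_all_transcripts=True,
        pos_in_cds=0.5,
        transcript_id="t",
    )


# ------------------------------------------------------- enrichment


def test_lof_in_roh_fraction_brute_force():
    blocks = [
        RohBlock("S0", "chr1", 1_000_000, 4_000_000),
        RohBlock("S1", "chr1", 2_000_000, 2_500_000),
        RohBlock("S2", "chr2", 1, 10_000_000),
    ]
    calls = [
        _call("chr1", 1_500_000, ["S0", "S1"]),
        _call("chr1", 2_200_000, ["S0", "S1", "S2"]),
        _call("chr2", 5_000_000, ["S2"]),
    ]
    cutoff = 400_000

    def oracle():
        num = den = 0
        for c in calls:
            for s in c.carriers_hom:
                den += 1
                for b in blocks:
                    if (
                        b.sample == s
                        and b.chrom == c.variant.chrom
                        and b.length_bp >= cutoff
                        and b.contains(c.variant.pos)
                    ):
                        num += 1
                        break
        return num / den

    got = lof_in_roh_fraction(calls, blocks, cutoff)
    assert got == pytest.approx(oracle())
    # no qualifying blocks -> 0; everything inside -> 1
    assert lof_in_roh_fraction(calls, [], 1) == 0.0
    assert (
        lof_in_roh_fraction(
            [_call("chr1", 10, ["S0"])],
            [RohBlock("S0", "chr1", 1, 100)],
            1,
        )
        == 1.0
    )
    with pytest.raises(DataError):
        lof_in_roh_fraction([], blocks, 1)


def test_enrichment_gain_values():
    # the headline cohort numbers: 14.4% of LoF instances inside the
    # autozygome vs 7.4% genomic coverage -> ~95% above random expectation
    assert enrichment_gain(0.144, 0.074) == pytest.approx(94.59, abs=0.01)
    assert round(enrichment_gain(0.144, 0.074)) == 95
    assert enrichment_gain(0.3, 0.3) == 0.0
    assert enrichment_gain(0.0, 0.25) == -100.0
    with pytest.raises(DataError):
        enrichment_gain(0.1, 0.0)


def test_enrichment_curve_single_individual_fixture():
    """Whole curve equals a hand-computed table for one individual."""
    genome = 10_000_000
    blocks = [
        RohBlock("S0", "chr1", 1, 1_000_000),        # 1 Mb
        RohBlock("S0", "chr1", 5_000_001, 8_000_000),  # 3 Mb
    ]
    calls = [
        _call("chr1", 500_000, ["S0"]),    # inside the 1 Mb block
        _call("chr1", 6_000_000, ["S0"]),  # inside the 3 Mb block
        _call("chr1", 9_500_000, ["S0"]),  # outside any block
    ]
    pts = enrichment_curve(
        calls, blocks, [500_000, 2_000_000, 4_000_000], genome, samples=["S0"]
    )
    # cutoff 0.5 Mb: both blocks qualify: 2/3 inside, coverage 4/10
    assert pts[0].lof_fraction == pytest.approx(2 / 3)
    assert pts[0].coverage_fraction == pytest.approx(0.4)
    assert pts[0].gain_percent == pytest.approx(100 * (2 / 3 / 0.4 - 1))
    # cutoff 2 Mb: only the 3 Mb block: 1/3 inside, coverage 0.3
    assert pts[1].lof_fraction == pytest.approx(1 / 3)
    assert pts[1].coverage_fraction == pytest.approx(0.3)
    # cutoff 4 Mb: nothing qualifies
    assert pts[2].lof_fraction == 0.0
    assert pts[2].coverage_fraction == 0.0
    assert np.isnan(pts[2].gain_percent)
    # coverage is monotone non-increasing in the cutoff
    covs = [p.coverage_fraction for p in pts]
    assert covs == sorted(covs, reverse=True)
    with pytest.raises(DataError):
        enrichment_curve(calls, blocks, [2, 1], genome)


def test_gain_invariant_to_relabeling_and_row_order():
    rng = np.random.default_rng(8)
    samples = [f"S{i}" for i in range(10)]
    blocks = [
        RohBlock(s, "chr1", int(a), int(a) + 2_000_000)
        for s in samples
        for a in rng.integers(1, 5_000_000, size=2)
    ]
    calls = [
        _call("chr1", int(p), rng.choice(samples, size=3, replace=False))
        for p in rng.integers(1, 9_000_000, size=20)
    ]
    f1 = lof_in_roh_fraction(calls, blocks, 1_000_000)
    # shuffle rows and relabel samples consistently
    mapping = {s: f"X{i}" for i, s in enumerate(samples)}
    calls2 = [
        _call(c.variant.chrom, c.variant.pos, [mapping[s] for s in c.carriers_hom])
        for c in calls
    ]
    rng.shuffle(calls2)
    blocks2 = [
        RohBlock(mapping[b.sample], b.chrom, b.start_bp, b.end_bp) for b in blocks
    ]
    rng.shuffle(blocks2)
    assert lof_in_roh_fraction(calls2, blocks2, 1_000_000) == pytest.approx(f1)


# ------------------------------------------------------- binomial bias


def _bias_setup(k, m, p0, genome=10_000_000):
    """Carriers with coverage exactly p0; m of them have the variant inside."""
    pos = 100
    blocks = []
    length = int(p0 * genome)
    carriers = [f"S{i}" for i in range(k)]
    for i, s in enumerate(carriers):
        if i < m:
            blocks.append(RohBlock(s, "chr1", 1, length))  # covers pos
        else:
            blocks.append(RohBlock(s, "chr1", 5_000_001, 5_000_000 + length))
    call = _call("chr1", pos, carriers)
    return call, blocks, genome


def test_bias_closed_forms():
    call, blocks, genome = _bias_setup(k=10, m=10, p0=0.1)
    r = allele_autozygome_bias(call, blocks, genome, min_length_bp=1)
    assert r.p_inside == pytest.approx(1e-10, rel=1e-6)
    assert r.classification == "inside_biased"
    call, blocks, genome = _bias_setup(k=1, m=0, p0=0.5)
    r = allele_autozygome_bias(call, blocks, genome, min_length_bp=1)
    assert r.p_outside == pytest.approx(0.5)
    assert r.classification == "unclassified"


def bias_enumeration_oracle(k, m, p0):
    """Tail probabilities by explicit enumeration of all 2^k carrier
    inside/outside configurations."""
    p_inside = p_outside = 0.0
    for config in itertools.product([0, 1], repeat=k):
        w = 1.0
        for z in config:
            w *= p0 if z else (1 - p0)
        if sum(config) >= m:
            p_inside += w
        if sum(config) <= m:
            p_outside += w
    return p_inside, p_outside


@pytest.mark.parametrize("k,m,p0", [(5, 2, 0.074), (8, 3, 0.2), (10, 1, 0.077)])
def test_bias_vs_enumeration(k, m, p0):
    call, blocks, genome = _bias_setup(k=k, m=m, p0=p0)
    r = allele_autozygome_bias(call, blocks, genome, min_length_bp=1)
    assert r.k == k and r.m == m
    assert r.p0 == pytest.approx(p0, abs=1e-9)
    pi, po = bias_enumeration_oracle(k, m, p0)
    assert r.p_inside == pytest.approx(pi, rel=1e-9)
    assert r.p_outside == pytest.approx(po, rel=1e-9)


def test_bias_degenerate_p0():
    call = _call("chr1", 100, ["S0", "S1"])
    r = allele_autozygome_bias(call, [], 1_000_000, min_length_bp=1)
    assert r.degenerate
    assert r.classification == "outside_biased"


# ------------------------------------------------------- rank tests


def test_exact_mw_example():
    # complete separation of 3 vs 3: U = 0, exact two-sided p = 2/20 = 0.1
    assert mann_whitney_u([1, 2, 3], [4, 5, 6]) == 0
    assert exact_mann_whitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_identical_groups_p_one():
    x = [2.0, 2.0, 2.0, 2.0]
    res = compare_frequency_distributions({"a": x, "b": list(x)})
    assert res.group_medians["a"] == res.group_medians["b"]
    assert res.pairwise_mw_p[("a", "b")] == pytest.approx(1.0)
    assert res.kruskal_wallis_p == pytest.approx(1.0)


def mw_bitmask_oracle(x, y):
    """Full permutation enumeration via bitmasks (independent coding of the
    exact two-sided Mann-Whitney p)."""
    pooled = list(x) + list(y)
    n = len(pooled)
    n1 = len(x)
    u_obs = mann_whitney_u(x, y)
    le = ge = tot = 0
    for mask in range(1 << n):
        if bin(mask).count("1") != n1:
            continue
        xs = [pooled[i] for i in range(n) if mask >> i & 1]
        ys = [pooled[i] for i in range(n) if not mask >> i & 1]
        u = mann_whitney_u(xs, ys)
        tot += 1
        le += u <= u_obs + 1e-12
        ge += u >= u_obs - 1e-12
    return min(1.0, 2 * min(le, ge) / tot)


def test_exact_mw_equals_full_enumeration_small_groups():
    rng = np.random.default_rng(9)
    for n1 in range(1, 7):
        for n2 in range(1, 7):
            # integer draws so ties occur often
            x = rng.integers(0, 4, size=n1).tolist()
            y = rng.integers(0, 4, size=n2).tolist()
            assert exact_mann_whitney_p(x, y) == pytest.approx(
                mw_bitmask_oracle(x, y)
            )


def test_exact_mw_matches_scipy_when_tie_free():
    rng = np.random.default_rng(10)
    for _ in range(20):
        x = rng.normal(size=int(rng.integers(2, 7))).tolist()
        y = rng.normal(size=int(rng.integers(2, 7))).tolist()
        ours = exact_mann_whitney_p(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(float(ref), abs=1e-9)


def test_compare_frequency_distributions_errors():
    with pytest.raises(DataError):
        compare_frequency_distributions({"a": [1.0]})
    with pytest.raises(DataError):
        compare_frequency_distributions({"a": [1.0], "b": []})


def test_spectrum_ordering_detected():
    rng = np.random.default_rng(11)
    groups = {
        "lof": rng.beta(1.6, 43.0, size=300).tolist(),
        "nonsyn": rng.beta(1.6, 18.6, size=300).tolist(),
        "syn": rng.beta(1.6, 13.0, size=300).tolist(),
    }
    res = compare_frequency_distributions(groups)
    assert (
        res.group_medians["lof"]
        < res.group_medians["nonsyn"]
        < res.group_medians["syn"]
    )
    assert res.kruskal_wallis_p < 0.05


# ------------------------------------------------------- carrier burden


def test_carrier_burden_examples():
    df = pd.DataFrame({"gene": ["g1", "g2"], "sample": ["A", "A"]})
    mean, se, median, counts = carrier_burden(df, ["g1", "g2"], ["A", "B"])
    assert (mean, median) == (1.0, 1.0)
    assert counts == {"A": 2, "B": 0}
    empty = pd.DataFrame({"gene": [], "sample": []})
    mean, se, median, _ = carrier_burden(empty, ["g1"], ["A", "B"])
    assert (mean, se, median) == (0.0, 0.0, 0.0)
    with pytest.raises(DataError):
        carrier_burden(df, [], ["A"])


def test_carrier_burden_hand_enumeration():
    rows = [
        ("g1", "A"), ("g1", "A"), ("g2", "A"),   # A: 2 distinct listed genes
        ("g3", "B"),                             # g3 not listed: B counts 0
        ("g1", "C"), ("g4", "C"),                # C: 2 (g4 listed)
        ("g2", "D"),                             # D: 1
    ]
    df = pd.DataFrame(rows, columns=["gene", "sample"])
    genes = ["g1", "g2", "g4"]
    samples = ["A", "B", "C", "D", "E"]
    mean, se, median, counts = carrier_burden(df, genes, samples)
    expected = {"A": 2, "B": 0, "C": 2, "D": 1, "E": 0}
    assert counts == expected
    vec = np.array(list(expected.values()), float)
    assert mean == pytest.approx(vec.mean())
    assert se == pytest.approx(vec.std(ddof=1) / np.sqrt(5))
    assert median == pytest.approx(1.0)
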