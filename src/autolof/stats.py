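"""Autozygome statistics: LoF enrichment inside ROHs, per-allele bias
tests, frequency-spectrum comparisons, and carrier burden.

The central quantity is the *enrichment gain* at an ROH length cutoff L:

    gain(L) = 100 * (f_LoF(L) / c(L) - 1)

where f_LoF(L) is the fraction of homozygous-LoF allele instances
(variant x carrier pairs) whose position falls inside one of the carrier's
ROHs of length >= L, and c(L) is the mean per-individual fraction of the
genome covered by such ROHs. Under uniform placement of LoF alleles the
two match and the gain is 0; autozygosity drives it up because rare
recessive alleles become homozygous preferentially inside identical-by-
descent segments.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DataError, RohBlock
from .discovery import LofCall
from .roh import roh_coverage_fraction


# ------------------------------------------------------- interval lookup


class _BlockIndex:
    """Sorted-interval point lookup per (sample, chrom) at a length cutoff."""

    def __init__(self, blocks: list[RohBlock], min_length_bp: int):
        self._starts: dict[tuple[str, str], np.ndarray] = {}
        self._ends: dict[tuple[str, str], np.ndarray] = {}
        grouped: dict[tuple[str, str], list[RohBlock]] = {}
        for b in blocks:
            if b.length_bp >= min_length_bp:
                grouped.setdefault((b.sample, b.chrom), []).append(b)
        for key, blist in grouped.items():
            blist.sort(key=lambda b: b.start_bp)
            self._starts[key] = np.array([b.start_bp for b in blist])
            self._ends[key] = np.array([b.end_bp for b in blist])

    def contains(self, sample: str, chrom: str, pos: int) -> bool:
        starts = self._starts.get((sample, chrom))
        if starts is None:
            return False
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos <= self._ends[(sample, chrom)][i]


# ------------------------------------------------------- enrichment


def lof_in_roh_fraction(
    lof_table: list[LofCall],
    roh_blocks: list[RohBlock],
    min_length_bp: int,
    mode: str = "instance",
) -> float:
    """Fraction of homozygous-LoF alleles inside a carrier ROH >= cutoff.

    ``mode='instance'`` counts (variant, carrier) pairs - each homozygous
    occurrence of an allele is one trial. ``mode='variant'`` counts each
    distinct variant once, as inside when at least one of its carriers has
    it inside a qualifying ROH.
    """
    if not lof_table:
        raise DataError("empty LoF table: fraction undefined")
    index = _BlockIndex(roh_blocks, min_length_bp)
    if mode == "instance":
        num = den = 0
        for call in lof_table:
            for sample in call.carriers_hom:
                den += 1
                if index.contains(sample, call.variant.chrom, call.variant.pos):
                    num += 1
        return num / den
    if mode == "variant":
        inside = sum(
            any(
                index.contains(s, call.variant.chrom, call.variant.pos)
                for s in call.carriers_hom
            )
            for call in lof_table
        )
        return inside / len(lof_table)
    raise DataError(f"unknown mode {mode!r}")


def enrichment_gain(lof_fraction: float, coverage_fraction: float) -> float:
    """Percent gain of LoF recovery over genomic coverage at a cutoff."""
    if coverage_fraction <= 0:
        raise DataError("coverage_fraction must be > 0 for the gain to be defined")
    return 100.0 * (lof_fraction / coverage_fraction - 1.0)


@dataclass
class EnrichmentPoint:
    min_roh_length_bp: int
    lof_fraction: float
    coverage_fraction: float
    gain_percent: float


def enrichment_curve(
    lof_table: list[LofCall],
    roh_blocks: list[RohBlock],
    cutoffs: list[int],
    genome_size_bp: int,
    samples: list[str] | None = None,
    mode: str = "instance",
) -> list[EnrichmentPoint]:
    """One enrichment point per ascending ROH length cutoff."""
    if list(cutoffs) != sorted(cutoffs):
        raise DataError("cutoffs must be sorted ascending")
    points = []
    for cutoff in cutoffs:
        lf = lof_in_roh_fraction(lof_table, roh_blocks, cutoff, mode=mode)
        cov = roh_coverage_fraction(
            roh_blocks, cutoff, genome_size_bp, samples=samples
        )
        gain = enrichment_gain(lf, cov) if cov > 0 else float("nan")
        points.append(EnrichmentPoint(int(cutoff), lf, cov, gain))
    return points


def enrichment_frame(points: list[EnrichmentPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "min_roh_length_bp": [p.min_roh_length_bp for p in points],
            "lof_fraction": [p.lof_fraction for p in points],
            "coverage_fraction": [p.coverage_fraction for p in points],
            "gain_percent": [round(p.gain_percent, 1) for p in points],
        }
    )


# ------------------------------------------------------- binomial bias


@dataclass
class BiasResult:
    variant_key: tuple
    k: int
    m: int
    p0: float
    p_inside: float
    p_outside: float
    classification: str
    degenerate: bool = False


def allele_autozygome_bias(
    call: LofCall,
    roh_blocks: list[RohBlock],
    genome_size_bp: int,
    alpha: float = 0.1,
    min_length_bp: int = 2_000_000,
) -> BiasResult:
    """One-tailed exact binomial test of a single allele's autozygome bias.

    k carriers, m of which have the allele inside an ROH >= cutoff; the
    null inside-probability p0 is the mean per-carrier genome coverage by
    such ROHs. p_inside = P(X >= m) and p_outside = P(X <= m) for
    X ~ Binomial(k, p0), computed by exact tail summation.
    """
    k = len(call.carriers_hom)
    if k < 1:
        raise DataError("no carriers to test")
    index = _BlockIndex(roh_blocks, min_length_bp)
    m = sum(
        index.contains(s, call.variant.chrom, call.variant.pos)
        for s in call.carriers_hom
    )
    per_sample = roh_coverage_fraction(
        roh_blocks,
        min_length_bp,
        genome_size_bp,
        per_sample=True,
        samples=list(call.carriers_hom),
    )
    p0 = float(np.mean([per_sample[s] for s in call.carriers_hom]))
    if p0 <= 0.0 or p0 >= 1.0:
        forced = "outside_biased" if p0 <= 0.0 and m == 0 else (
            "inside_biased" if p0 >= 1.0 and m == k else "unclassified"
        )
        return BiasResult(call.variant.key, k, m, p0, 1.0, 1.0, forced, True)
    j = np.arange(k + 1)
    pmf = sps.binom.pmf(j, k, p0)
    p_inside = float(pmf[m:].sum())
    p_outside = float(pmf[: m + 1].sum())
    if p_inside < alpha:
        classification = "inside_biased"
    elif p_outside < alpha:
        classification = "outside_biased"
    else:
        classification = "unclassified"
    return BiasResult(call.variant.key, k, m, p0, p_inside, p_outside, classification)


def bias_frame(results: list[BiasResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.variant_key[0] for r in results],
            "pos": [r.variant_key[1] for r in results],
            "ref": [r.variant_key[2] for r in results],
            "alt": [r.variant_key[3] for r in results],
            "k": [r.k for r in results],
            "m": [r.m for r in results],
            "p0": [round(r.p0, 6) for r in results],
            "p_inside": [round(r.p_inside, 6) for r in results],
            "p_outside": [round(r.p_outside, 6) for r in results],
            "classification": [r.classification for r in results],
        }
    )


def bias_calibration_rate(
    n_alleles: int,
    seed: int,
    alpha: float = 0.1,
    min_length_bp: int = 2_000_000,
    config=None,
) -> float:
    """Null calibration of the bias test: fraction of uniformly placed
    alleles called inside-biased at the given alpha.

    Simulates a cohort's planted ROH structure, then places synthetic
    alleles uniformly at random (no autozygome enrichment) with randomly
    drawn carrier sets, and runs :func:`allele_autozygome_bias` on each.
    The discrete one-tailed binomial test should flag at most ~alpha.
    """
    from .core import VariantRecord
    from .simulate import CohortConfig, plant_roh_structure

    config = config or CohortConfig(seed=seed)
    rohs = plant_roh_structure(config)
    blocks = [b for bl in rohs.values() for b in bl]
    samples = sorted(rohs)
    chrom_names = [name for name, _ in config.genome]
    chrom_lens = np.array([length for _, length in config.genome], dtype=float)
    rng = np.random.default_rng(seed + 1)
    n_flagged = 0
    for _ in range(n_alleles):
        k = 1 + int(rng.poisson(2.5))
        carriers = tuple(
            rng.choice(samples, size=min(k, len(samples)), replace=False)
        )
        ci = int(rng.choice(len(chrom_names), p=chrom_lens / chrom_lens.sum()))
        pos = int(rng.integers(1, chrom_lens[ci]))
        call = LofCall(
            variant=VariantRecord(chrom=chrom_names[ci], pos=pos, ref="A", alt="T"),
            gene_id="g",
            klass="stop_gain",
            carriers_hom=carriers,
            carriers_het=(),
            affects_all_transcripts=True,
            pos_in_cds=0.5,
            transcript_id="t",
        )
        r = allele_autozygome_bias(
            call,
            blocks,
            config.genome_size_bp,
            alpha=alpha,
            min_length_bp=min_length_bp,
        )
        n_flagged += r.classification == "inside_biased"
    return n_flagged / n_alleles


# ------------------------------------------------------- rank tests


def mann_whitney_u(x, y) -> float:
    """U statistic for x against y, counting ties as half."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def exact_mann_whitney_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full permutation enumeration.

    Enumerates every split of the pooled sample into groups of the observed
    sizes, handles ties exactly, and doubles the smaller tail (capped at 1).
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)
    u_obs = mann_whitney_u(x, y)
    n_le = n_ge = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        u = mann_whitney_u(xs, ys)
        total += 1
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def mann_whitney_p(x, y, max_exact: int = 8) -> float:
    """Two-sided Mann-Whitney p: exact enumeration for small groups,
    tie-corrected normal approximation otherwise."""
    if len(x) == 0 or len(y) == 0:
        raise DataError("empty group in Mann-Whitney test")
    if len(x) <= max_exact and len(y) <= max_exact:
        return exact_mann_whitney_p(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


@dataclass
class FreqComparison:
    groups: dict[str, np.ndarray]
    group_medians: dict[str, float]
    kruskal_wallis_p: float
    pairwise_mw_p: dict[tuple[str, str], float]


def compare_frequency_distributions(
    groups: dict[str, list[float]], max_exact: int = 8
) -> FreqComparison:
    """Kruskal-Wallis across groups plus pairwise Mann-Whitney tests."""
    if len(groups) < 2:
        raise DataError("need at least two groups")
    arrays = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size == 0:
            raise DataError(f"group {name!r} is empty")
        arrays[name] = arr
    medians = {name: float(np.median(a)) for name, a in arrays.items()}
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:  # all observations identical: no evidence
        kw_p = 1.0
    else:
        kw_p = float(sps.kruskal(*arrays.values()).pvalue)
    pairwise = {}
    for a, b in itertools.combinations(sorted(arrays), 2):
        pairwise[(a, b)] = mann_whitney_p(arrays[a], arrays[b], max_exact)
    return FreqComparison(arrays, medians, kw_p, pairwise)


# ------------------------------------------------------- carrier burden


def carrier_burden(
    het_lof_table: pd.DataFrame,
    ardg_gene_list: list[str],
    samples: list[str],
) -> tuple[float, float, float, dict[str, int]]:
    """Per-genome count of recessive-disease genes carried heterozygously.

    ``het_lof_table`` holds (gene, sample) heterozygous-LoF pairs; only
    genes in ``ardg_gene_list`` count, distinct genes per sample. Returns
    (mean, standard error, median, per-sample counts incl. zeros).
    """
    if not ardg_gene_list:
        raise DataError("gene list is empty")
    ardg = set(ardg_gene_list)
    counts = {s: 0 for s in samples}
    if len(het_lof_table):
        sub = het_lof_table[het_lof_table["gene"].isin(ardg)]
        per = sub.groupby("sample")["gene"].nunique()
        for s, c in per.items():
            if s in counts:
                counts[s] = int(c)
    vec = np.array(list(counts.values()), dtype=float)
    mean = float(vec.mean())
    se = float(vec.std(ddof=1) / np.sqrt(len(vec))) if len(vec) > 1 else 0.0
    return mean, se, float(np.median(vec)), counts
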