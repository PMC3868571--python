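# Methods

This note documents the models, parameters, numerical choices and known
limitations of `autolof`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Loss-of-function definition and consequence calling

A variant is LoF only in the strict sense: a **stop-gain SNP** (a sense
codon mutated to TAA/TAG/TGA on the coding strand) or a **frameshifting
indel** (net coding-sequence length change not divisible by three).
Splice-site disruption, stop-loss, missense and in-frame indels are
classified but never counted as LoF. The classifier produces one
consequence call per transcript overlapping the variant; codon effects are
computed on the coding strand with the standard genetic code.

Conventions worth stating:

* Coordinates are 0-based half-open internally, converted to 1-based
  inclusive at every I/O boundary (VCF, GFF3, PLINK-style tables).
* VCF alleles are normalised by stripping the shared prefix (the anchor
  base); multi-allelic records are split into biallelic records on input.
* An indel's class is decided by its **in-CDS** inserted minus deleted
  length, so an indel straddling a CDS boundary is frameshift when the
  in-CDS part is non-mod-3. A pure insertion counts as coding only when
  its insertion point falls strictly between two CDS bases of a segment.
* `cds_offset` is the first affected CDS base in transcript orientation;
  `pos_in_cds = cds_offset / cds_length ∈ [0, 1)` is evaluated on the
  longest affected transcript (gene annotations do not designate a
  canonical transcript, so longest-CDS is the deterministic choice).
* A REF allele disagreeing with the FASTA is a data error: the variant is
  reported and skipped, never guessed.

### Rescue interactions

Two patterns cancel a candidate LoF and disqualify it (flag + score 0):

* **Complementary frameshifts** — two frameshifting indels on the same
  transcript, in the same homozygous carrier, within `rescue_window_bp`
  (default 200 bp; "nearby" is not a quantity the underlying analysis
  fixes, so it is a parameter), whose signed length changes sum to 0 mod 3.
  Both partners are flagged.
* **Same-codon rescue** — a stop-gain SNP co-occurring with another SNP in
  the same codon such that the jointly mutated codon is not a stop. Only
  the stop-gain is flagged; the partner keeps its own class.

Rescue detection runs per (gene, carrier) on homozygous calls; phase is
irrelevant in homozygous context. A variant rescued in any carrier is
excluded globally, matching an allele-level confirmed-variant table.

### Reference-artifact heuristic

When the alternate allele is homozygous in ≥ `artifact_threshold`
(default 0.90) of the cohort *and* the ancestral allele is unknown or
equals the alternate, the candidate most likely recovers the ancestral
state and the reference carries the derived, broken allele; it is flagged
`reference_artifact` and excluded. A near-fixed allele whose ancestral
state matches the reference is only flagged `high_frequency` (kept, since
high frequency alone is not evidence of an artifact). This rule is the
automatable core of what is otherwise a manual browser-level review;
judgment-based curation (conservation, suspected polymorphic loci) is out
of scope.

## Ablation score

Score 0–3 from two booleans: `A` (LoF on every transcript of the gene)
and `E` (`pos_in_cds ≤ 1 − tail_fraction`, default tail 10%):
3 = A∧E, 1 = ¬A∧¬E, 2 otherwise, 0 = disqualifying flag. The extremes are
externally given (3 = most likely full ablation; 1 = escape via an
unaffected alternative transcript *and* a last-10% position); treating a
single failing condition as the middle score is this package's completion
of the matrix, chosen as the only monotone two-condition design. A
position exactly at 90% counts as body, not tail; the boundary had to be
assigned somewhere and ties-to-body is the conservative direction.

## ROH calling

A deterministic maximal-run scan, not a sliding-window heuristic: per
sample and chromosome, missing calls and inter-SNP gaps above
`max_gap_bp` (default 1 Mb) split the site sequence into segments; within
a segment, homozygous runs are grown left to right with a heterozygosity
budget (`max_het`, default 0) and trimmed so blocks start and end on
homozygous calls. Blocks must span ≥ `min_length_bp` (default 100 kb) and
≥ `min_snps` (default 25) sites. With the default `max_het = 0` the output
is exactly the set of maximal homozygous runs; for `max_het > 0` maximal
runs can overlap, and the caller emits the greedy left-to-right disjoint
choice — a documented convention, chosen because it is oracle-checkable.
Block boundaries are the outermost SNPs of the run (not midpoints to the
flanking markers). Equivalence with PLINK's windowed caller is not
claimed. ROHs ≥ 2 Mb are treated as the autozygome; shorter runs are more
often identity-by-state and only enter coverage curves at lower cutoffs.

## Autozygome statistics

* **Enrichment.** `f_LoF(L)` counts (variant, carrier) pairs — allele
  *instances* — whose position lies inside one of that carrier's ROHs ≥ L;
  the baseline `c(L)` is the mean per-individual genome fraction in such
  ROHs, with block-less individuals counted as zero. The gain is
  `100·(f/c − 1)`, reported to one decimal. A per-distinct-variant mode
  (`mode="variant"`: a variant is inside if any carrier has it inside) is
  provided because instance-vs-variant counting is a genuine ambiguity;
  instance mode is the default.
* **Bias test.** For one allele with `k` homozygous carriers, `m` of them
  inside the autozygome, the null inside-probability `p₀` is the mean
  coverage among *that allele's carriers* (not the cohort mean): carriers
  with more autozygous genome are expected to harbour the allele inside
  more often, and conditioning on the carriers removes that nuisance
  heterogeneity. `p_inside = P(X ≥ m)` and `p_outside = P(X ≤ m)` for
  `X ~ Binomial(k, p₀)` by explicit probability-mass summation; a tail
  below `alpha` (default 0.1, uncorrected — the screen is deliberately
  liberal and per-allele) classifies the allele as inside- or
  outside-biased. `p₀ ∈ {0, 1}` is degenerate: the classification is
  forced and flagged rather than computed.
* **Rank tests.** Pairwise Mann–Whitney is exact — full enumeration of
  every split of the pooled sample, ties handled by half-counting, two
  sided via doubling the smaller tail — whenever both groups have ≤ 8
  observations, and the tie-corrected normal approximation otherwise.
  Kruskal–Wallis comes from scipy; an all-identical pooled sample returns
  p = 1 rather than an error.
* **Carrier burden.** Per individual, the number of *distinct* listed
  recessive-disease genes with at least one heterozygous LoF; reported as
  mean ± s.e. (sd/√n) and median over all samples including zeros.

## Synthetic cohort generator

The generator is an **artifact of the analysis, not a population-genetic
simulator**: it plants the statistical structure the pipeline assumes
directly, with no pedigrees, recombination, mutation model or sequencing
errors. Defaults reproduce the study conditions of a consanguineous
exome cohort: 77 individuals, mean autozygosity 7.7% of the genome in
ROHs ≥ 2 Mb, allele-frequency medians ordered LoF (≈3.9%) <
nonsynonymous (≈6.5%) < synonymous (≈9.1%), a planted autozygome
enrichment gain of 95%, and a heterozygous carrier burden of ≈1.9
disease-gene alleles per genome. Genome scale is a toy — 2 chromosomes ×
30 Mb, 60 genes, ~1,800 coding sites plus 6,000 intergenic array sites
(~10 kb spacing, scaled-down SNP-chip density; fine enough that
called-block boundaries track planted blocks to within a few markers) —
keeping the full pipeline under ~15 s.

Mechanisms, in generation order:

1. **Reference and genes.** Uniform random sequence; genes placed in
   evenly spaced slots (1 Mb chromosome margins), each with 3–5
   codon-aligned exons (every exon length divisible by 3, codons never
   straddle junctions), a clean ORF (ATG, no internal stop, single
   terminal stop), random strand. 40% of genes get a second transcript
   that skips one internal exon — codon alignment guarantees the skipped
   product is still a clean ORF, and gives the scorer genuinely
   alternative-spliced exons to detect.
2. **ROH planting.** Per individual, a target autozygous fraction
   `c_i ~ Gamma(shape 4, mean 7.7%)` (range roughly <1%–22%), realised as
   non-overlapping blocks of length 2 Mb + Exp(2.5 Mb); the final block is
   trimmed (or planted with probability `remaining/2 Mb`) so the expected
   total equals `c_i × genome` exactly. A Poisson(12) number of short
   0.1–2 Mb blocks models identity-by-state runs and populates the
   low-cutoff end of the coverage curve. Lengths are stand-ins; no length
   distribution is externally specified.
3. **Sites and frequencies.** Per-class beta spectra (synonymous
   Beta(1.6, 13.0), nonsynonymous Beta(1.6, 18.6), LoF classes
   Beta(1.6, 43.0), array Beta(2, 4)), calibrated once so *realised*
   cohort medians land on the target ordering (LoF realised frequencies
   are inflated slightly by the heterozygous-carrier mechanism, hence the
   smaller beta median). Stop-gains are planted at codons one substitution
   away from a stop; synonymous/nonsynonymous at codons admitting the
   wanted effect; frameshifts as 1-bp insertions or 2-bp deletions wholly
   inside an exon. All planted frameshifts have net length change ≡ +1
   mod 3, so no pair of independent plants can ever sum to 0 mod 3 —
   complementary-rescue flags can only come from the dedicated rescue
   planter, which keeps its pairs ≥ 250 bp away from clean frameshifts in
   the same gene.
4. **Genotypes.** Inside any planted ROH an individual is homozygous by
   construction (hom-alt with probability equal to the site frequency —
   one haplotype draw — else hom-ref); outside, Hardy–Weinberg.
   For LoF sites the hom-alt carrier probability is split between
   individuals whose autozygome covers the site (`q_in = f·t/c_site`) and
   the rest (`q_out = f·(1−t)/(1−c_site)`) with `t = (1+g)·c̄`, where `c̄`
   is the cohort's mean ≥2 Mb coverage — the same baseline the enrichment
   statistic divides by. This makes each carrier's inside-indicator an
   independent Bernoulli(t), so the planted gain `g` is recovered without
   bias and the pooled inside-count is exactly binomial (which is what the
   parameter-recovery tests use as their Monte-Carlo CI). Heterozygous LoF
   carriers are added outside ROHs at rate `0.42·f`, calibrated to the
   target carrier burden.
5. **Planted filter targets.** Two complementary frameshift pairs, two
   same-codon rescues and two near-fixed stop-gains whose ancestral allele
   equals the alternate (reference artifacts) are planted with forced
   carriers and excluded from the knockout ground truth; the discovery
   filters must remove exactly these.

Ground truth (planted ROHs, knockouts, per-site class and frequency,
flagged sites, disease-gene list) is emitted alongside FASTA/GFF3/VCF and
drives the recovery tests: reclassifying the emitted files reproduces the
class labels exactly, and the confirmed table equals planted knockouts
minus planted rescues/artifacts.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: linkage disequilibrium and
haplotype sharing, genotyping/sequencing error, variable exome capture,
population structure, selection against LoF (frequencies are
placement-independent, so the real-data pattern of inside-biased alleles
being rarer does not arise), splice-region biology, and any correlation
between a gene's LoF tolerance and its variant density. One structural
consequence: skipped exons are internal while the ORF tail lies almost
always in the final exon, so the ¬A∧¬E cell (score 1) essentially never
occurs in synthetic cohorts; the scorer's full matrix is covered by
direct unit tests instead.

## Pipeline and reproducibility

`autolof run` executes simulate → load (re-reading its own FASTA, GFF3
and VCF through the standard parsers, so every run exercises the I/O
round trip) → ROH (array sites) → discover → score → stats, persists
every intermediate table, and writes `summary.json` plus a
parameter/log file. All randomness flows from one integer seed through
`numpy.random.default_rng` child streams; identical config + seed gives
byte-identical outputs (no timestamps in any artifact). Stage failures
abort with the stage name; partial outputs are retained. Exit codes:
0 success, 1 data error, 2 configuration error.

Problem sizes used by the test suite and `scripts/acceptance.py` — the
default 77-individual cohort for end-to-end runs, three replicate cohorts
per planted gain value, n = 500 individuals for autozygosity recovery
(ROH planting only), and 2,500 simulated alleles for the bias-test null
calibration — were chosen to make Monte-Carlo error small relative to the
tolerances being checked while keeping a full run interactive.

## Known limitations

* The rescue window (200 bp), artifact threshold (0.90) and ROH defaults
  (`min_snps` 25, `max_het` 0, `max_gap` 1 Mb) are reasonable
  conventions, not fitted values; all are configurable.
* The enrichment curve uses called blocks, whose boundaries sit at the
  outermost spanned markers: planted blocks near a length cutoff can be
  called just below it, and chance homozygous flanking markers can extend
  blocks slightly — a ~few-percent attenuation of curve quantities at any
  fixed cutoff relative to the planted truth.
* `heterozygous_lof_carriers` applies no rescue/artifact filtering
  (heterozygous calls carry no homozygous rescue context); with real data
  its output should be treated as a candidate list, as any carrier-burden
  screen would be.
* No multiple-testing correction is applied to the per-allele bias tests;
  they are a deliberately liberal screen at raw p < 0.1.
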