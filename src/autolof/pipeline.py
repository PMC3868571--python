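"""End-to-end orchestration: simulate -> ROH -> discover -> score -> stats.

Every stage persists its table under the output directory, and the run
ends with a machine-readable ``summary.json`` whose numbers are all
recomputable from those tables. Identical config and seed give
byte-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .core import HET, DataError, GenotypeMatrix, is_autosome
from .discovery import (
    LOF_CLASSES,
    build_homozygous_lof_table,
    classify_variant,
    heterozygous_lof_carriers,
    lof_table_to_frame,
)
from .roh import RohParams, call_roh, roh_coverage_fraction
from .scoring import score_table
from .simulate import CohortConfig, simulate_cohort, write_cohort
from .stats import (
    allele_autozygome_bias,
    bias_frame,
    carrier_burden,
    compare_frequency_distributions,
    enrichment_curve,
    enrichment_frame,
    mann_whitney_p,
)

DEFAULT_CUTOFFS = [
    100_000, 200_000, 500_000, 700_000, 1_000_000, 1_500_000,
    2_000_000, 3_000_000, 5_000_000, 7_000_000, 10_000_000,
]


@dataclass
class RunConfig:
    out_dir: str = "autolof_run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)   # CohortConfig overrides
    roh: dict = field(default_factory=dict)      # RohParams overrides
    tail_fraction: float = 0.10
    alpha: float = 0.1
    cutoffs: list[int] = field(default_factory=lambda: list(DEFAULT_CUTOFFS))
    autozygous_cutoff_bp: int = 2_000_000
    autosomes_only: bool = True
    instance_mode: str = "instance"
    inputs: dict = field(default_factory=dict)   # optional pre-existing files

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise DataError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def summarize_per_genome(lof_table, n_samples: int) -> tuple[float, dict]:
    """Mean number of knocked-out genes per genome plus the distribution.

    Counts distinct (gene, sample) pairs - two LoF alleles of one gene in
    the same individual are one knockout.
    """
    if n_samples <= 0:
        raise DataError("n_samples must be > 0")
    pairs = set()
    per_sample: dict[str, set] = {}
    for call in lof_table:
        for s in call.carriers_hom:
            pairs.add((call.gene_id, s))
            per_sample.setdefault(s, set()).add(call.gene_id)
    counts = sorted(len(v) for v in per_sample.values())
    dist = {str(c): counts.count(c) for c in sorted(set(counts))}
    return len(pairs) / n_samples, dist


def _variant_class_groups(matrix, models, reference, autosomes_only):
    """Per-variant frequency vectors by consequence class (for the
    frequency-spectrum comparison)."""
    from .discovery import ReferenceMismatchError, allele_frequency

    groups = {"lof": [], "nonsynonymous": [], "synonymous": []}
    priority = ["stop_gain", "frameshift_indel", "nonsynonymous", "synonymous"]
    for i in range(matrix.n_sites):
        v = matrix.variant(i)
        if autosomes_only and not is_autosome(v.chrom):
            continue
        try:
            calls = classify_variant(v, models, reference)
        except ReferenceMismatchError:
            continue
        classes = {c.klass for c in calls}
        klass = next((k for k in priority if k in classes), None)
        if klass is None:
            continue
        af, _, _ = allele_frequency(v)
        if af <= 0:
            continue
        key = "lof" if klass in LOF_CLASSES else klass
        groups[key].append(af)
    return groups


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def logline(msg: str) -> None:
        log.append(msg)

    stage = "simulate"
    try:
        if config.inputs:
            paths = dict(config.inputs)
            logline(f"using provided inputs: {sorted(paths)}")
        else:
            cohort_cfg = CohortConfig(seed=config.seed, **config.cohort)
            cohort = simulate_cohort(cohort_cfg)
            paths = write_cohort(cohort, out / "cohort")
            logline(
                f"simulated cohort: n={cohort_cfg.n_individuals}, "
                f"seed={config.seed}"
            )

        stage = "load"
        reference = io.read_fasta(paths["fasta"])
        models = io.read_gff3(paths["gff3"], reference)
        matrix = io.read_vcf(paths["vcf"])
        array_path = paths.get("array_vcf") or paths.get("genotypes")
        array = io.read_vcf(array_path) if array_path else matrix
        ancestral = (
            io.read_ancestral_tsv(paths["ancestral"])
            if paths.get("ancestral")
            else {}
        )
        ardg = (
            io.read_gene_list(paths["ardg"]) if paths.get("ardg") else []
        )
        genome_size = sum(len(s) for s in reference.values())

        stage = "roh"
        roh_params = RohParams(**config.roh)
        blocks = call_roh(array, roh_params)
        io.write_roh_tsv(blocks, out / "roh.hom.tsv")

        stage = "discover"
        stage_counts: dict = {}
        skipped: list = []
        table = build_homozygous_lof_table(
            matrix,
            models,
            reference,
            autosomes_only=config.autosomes_only,
            ancestral=ancestral,
            report_skipped=skipped,
            stage_counts=stage_counts,
        )
        for msg in skipped:
            logline(f"skipped variant: {msg}")

        stage = "score"
        table = score_table(table, tail_fraction=config.tail_fraction)
        lof_frame = lof_table_to_frame(table)
        lof_frame.to_csv(out / "lof_table.tsv", sep="\t", index=False)

        stage = "stats"
        curve = enrichment_curve(
            table,
            blocks,
            config.cutoffs,
            genome_size,
            samples=matrix.samples,
            mode=config.instance_mode,
        )
        enrichment_frame(curve).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        at_cut = next(
            p for p in curve if p.min_roh_length_bp == config.autozygous_cutoff_bp
        )

        bias = [
            allele_autozygome_bias(
                c, blocks, genome_size,
                alpha=config.alpha,
                min_length_bp=config.autozygous_cutoff_bp,
            )
            for c in table
        ]
        bias_frame(bias).to_csv(out / "bias.tsv", sep="\t", index=False)
        bias_counts = {
            cls: sum(1 for r in bias if r.classification == cls)
            for cls in ("inside_biased", "outside_biased", "unclassified")
        }
        freq_by_call = {c.variant.key: c.allele_freq for c in table}
        inside_f = [
            freq_by_call[r.variant_key]
            for r in bias
            if r.classification == "inside_biased"
        ]
        outside_f = [
            freq_by_call[r.variant_key]
            for r in bias
            if r.classification == "outside_biased"
        ]
        inside_outside = {}
        if inside_f and outside_f:
            inside_outside = {
                "median_freq_inside_biased": float(np.median(inside_f)),
                "median_freq_outside_biased": float(np.median(outside_f)),
                "mw_p": mann_whitney_p(inside_f, outside_f),
            }

        groups = _variant_class_groups(
            matrix, models, reference, config.autosomes_only
        )
        freqs = compare_frequency_distributions(groups)
        with open(out / "freqs.tsv", "w") as fh:
            fh.write("group\tn\tmedian\n")
            for name in sorted(groups):
                fh.write(
                    f"{name}\t{len(groups[name])}\t"
                    f"{freqs.group_medians[name]:.6f}\n"
                )

        het_table = heterozygous_lof_carriers(
            matrix, models, reference, config.autosomes_only
        )
        het_table.to_csv(out / "het_lof.tsv", sep="\t", index=False)
        carriers = {}
        if ardg:
            mean, se, median, _ = carrier_burden(het_table, ardg, matrix.samples)
            carriers = {
                "mean_ardg_per_genome": mean,
                "se": se,
                "median": median,
                "n_ardg_genes_listed": len(ardg),
                "n_ardg_genes_hit": int(
                    het_table[het_table["gene"].isin(set(ardg))]["gene"].nunique()
                )
                if len(het_table)
                else 0,
            }

        mean_ko, ko_dist = summarize_per_genome(table, matrix.n_samples)

        summary = {
            "seed": config.seed,
            "n_samples": matrix.n_samples,
            "genome_size_bp": genome_size,
            "filter_cascade": stage_counts,
            "n_confirmed_lof_variants": len(table),
            "n_distinct_genes": len({c.gene_id for c in table}),
            "mean_knockouts_per_genome": round(mean_ko, 4),
            "knockout_distribution": ko_dist,
            "score_shares": {
                str(s): round(
                    sum(1 for c in table if c.score == s) / max(1, len(table)), 4
                )
                for s in (0, 1, 2, 3)
            },
            "roh": {
                "n_blocks": len(blocks),
                "mean_autozygosity_at_cutoff": round(
                    roh_coverage_fraction(
                        blocks,
                        config.autozygous_cutoff_bp,
                        genome_size,
                        samples=matrix.samples,
                    ),
                    6,
                ),
            },
            "enrichment_at_cutoff": {
                "min_roh_length_bp": at_cut.min_roh_length_bp,
                "lof_fraction": round(at_cut.lof_fraction, 6),
                "coverage_fraction": round(at_cut.coverage_fraction, 6),
                "gain_percent": round(at_cut.gain_percent, 1),
            },
            "enrichment_curve": [
                {
                    "min_roh_length_bp": p.min_roh_length_bp,
                    "lof_fraction": round(p.lof_fraction, 6),
                    "coverage_fraction": round(p.coverage_fraction, 6),
                    "gain_percent": round(p.gain_percent, 1)
                    if np.isfinite(p.gain_percent)
                    else None,
                }
                for p in curve
            ],
            "bias_classifications": bias_counts,
            "inside_vs_outside_freq": {
                k: round(v, 6) for k, v in inside_outside.items()
            },
            "frequency_comparison": {
                "medians": {
                    k: round(v, 6) for k, v in freqs.group_medians.items()
                },
                "kruskal_wallis_p": float(f"{freqs.kruskal_wallis_p:.3e}"),
                "pairwise_mw_p": {
                    f"{a}_vs_{b}": float(f"{p:.3e}")
                    for (a, b), p in freqs.pairwise_mw_p.items()
                },
            },
            "carrier_burden": {
                k: (round(v, 4) if isinstance(v, float) else v)
                for k, v in carriers.items()
            },
        }
    except Exception as exc:
        (out / "run_log.txt").write_text(
            "\n".join(log + [f"FAILED at stage {stage}: {exc}"]) + "\n"
        )
        raise DataError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    params_echo = {
        "seed": config.seed,
        "roh_params": asdict(roh_params),
        "tail_fraction": config.tail_fraction,
        "alpha": config.alpha,
        "cutoffs": config.cutoffs,
        "autosomes_only": config.autosomes_only,
        "instance_mode": config.instance_mode,
    }
    log.append("parameters: " + json.dumps(params_echo, sort_keys=True))
    log.append("stages completed: simulate/load/roh/discover/score/stats")
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return summary
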