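"""Report-level loading and summarising of confirmed-variant tables.

These helpers consume the TSV the pipeline writes (or a user-supplied
table with the same column vocabulary, e.g. a converted supplementary
table of confirmed homozygous LoF variants) and recompute the headline
cohort numbers from it: variant and gene counts, mean knocked-out genes
per genome, and ablation-score shares.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DataError, VariantRecord
from .discovery import LofCall

_COLUMN_ALIASES = {
    "gene": "Gene",
    "chr": "Chr",
    "chrom": "Chr",
    "location": "Location",
    "position": "Location",
    "pos": "Location",
    "score": "Score",
    "ref allele": "Ref Allele",
    "refallele": "Ref Allele",
    "alt allele": "Alt Allele",
    "altallele": "Alt Allele",
    "annotation": "Annotation",
    "ngs seen in": "NGS Seen in",
    "observed freq": "Observed Freq",
    "obsfreq": "Observed Freq",
    "pos in cds": "Pos in CDS",
    "on all transcripts": "On All Transcripts",
    "flags": "Flags",
    "carriers": "Carriers",
}


def load_lof_table(path) -> pd.DataFrame:
    """Read a confirmed-LoF TSV, normalising header spelling."""
    df = pd.read_csv(path, sep="\t", dtype={"Chr": str, "chr": str})
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _COLUMN_ALIASES:
            rename[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=rename)
    if "Gene" not in df.columns:
        raise DataError(f"{path}: no Gene column found")
    return df


def summarize_lof_table(df: pd.DataFrame, n_samples: int) -> dict:
    """Headline numbers of a confirmed homozygous-LoF table.

    Mean knocked-out genes per genome counts distinct (gene, sample)
    pairs when per-variant carrier lists are available; otherwise it
    falls back to summed per-variant carrier counts (an upper bound when
    one sample carries two LoF alleles of the same gene).
    """
    if n_samples <= 0:
        raise DataError("n_samples must be > 0")
    out: dict = {
        "n_variants": int(len(df)),
        "n_distinct_genes": int(df["Gene"].nunique()),
    }
    if "Carriers" in df.columns and df["Carriers"].notna().any():
        pairs = set()
        for gene, carriers in zip(df["Gene"], df["Carriers"].fillna("")):
            for s in str(carriers).split(","):
                if s:
                    pairs.add((gene, s))
        out["mean_knockouts_per_genome"] = len(pairs) / n_samples
    elif "NGS Seen in" in df.columns:
        out["mean_knockouts_per_genome"] = float(
            df["NGS Seen in"].sum() / n_samples
        )
    if "Score" in df.columns:
        scores = pd.to_numeric(df["Score"], errors="coerce").dropna()
        if len(scores):
            out["share_score_3"] = float((scores == 3).mean())
            out["share_score_1"] = float((scores == 1).mean())
    return out


def summarize_ardg_table(df: pd.DataFrame) -> dict:
    """Distinct-gene count of a heterozygous-carrier (ARDG) table."""
    gene_col = next(
        (c for c in df.columns if c.strip().lower() in ("gene", "gene_id")), None
    )
    if gene_col is None:
        raise DataError("no Gene column in ARDG table")
    return {"n_distinct_ardg_genes": int(df[gene_col].nunique())}


def frame_to_lofcalls(df: pd.DataFrame) -> list[LofCall]:
    """Rebuild minimal LofCall objects from a table with a Carriers column
    (enough for the enrichment and bias statistics)."""
    if "Carriers" not in df.columns:
        raise DataError("table lacks a Carriers column; cannot rebuild calls")
    calls = []
    for r in df.itertuples(index=False):
        d = {c: getattr(r, f) for c, f in zip(df.columns, r._fields)}
        carriers = tuple(s for s in str(d["Carriers"]).split(",") if s)
        score = d.get("Score")
        calls.append(
            LofCall(
                variant=VariantRecord(
                    chrom=str(d["Chr"]),
                    pos=int(d["Location"]),
                    ref=str(d["Ref Allele"]),
                    alt=str(d["Alt Allele"]),
                ),
                gene_id=str(d["Gene"]),
                klass=str(d.get("Annotation", "")),
                carriers_hom=carriers,
                carriers_het=(),
                affects_all_transcripts=bool(d.get("On All Transcripts", True)),
                pos_in_cds=float(d.get("Pos in CDS", 0.0)),
                transcript_id="",
                score=int(score) if score not in (None, "") and not pd.isna(score) else None,
                hom_freq=float(d.get("Observed Freq", 0.0)),
            )
        )
    return calls
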