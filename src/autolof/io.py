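"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, VCF reading via cyvcf2, GFF3 reading via gffutils.
All writers emit sorted, deterministic plain text so identical inputs give
byte-identical files.
"""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import HET, HOM_ALT, HOM_REF, MISSING, DataError, GenotypeMatrix, RohBlock
from .genemodels import GeneModelSet, Transcript

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


# ---------------------------------------------------------------- FASTA

def write_fasta(reference: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- GFF3

def write_gff3(transcripts: list[Transcript], path: str | os.PathLike) -> None:
    """Emit gene/mRNA/exon/CDS features, 1-based inclusive coordinates."""
    lines = ["##gff-version 3"]
    by_gene: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gene_id in sorted(by_gene):
        ts = sorted(by_gene[gene_id], key=lambda t: t.transcript_id)
        chrom, strand = ts[0].chrom, ts[0].strand
        gs = min(t.span[0] for t in ts) + 1
        ge = max(t.span[1] for t in ts)
        lines.append(
            f"{chrom}\t.\tgene\t{gs}\t{ge}\t.\t{strand}\t.\tID={gene_id}"
        )
        for t in ts:
            ts0, te0 = t.span
            lines.append(
                f"{chrom}\t.\tmRNA\t{ts0 + 1}\t{te0}\t.\t{strand}\t.\t"
                f"ID={t.transcript_id};Parent={gene_id}"
            )
            for i, (s, e) in enumerate(t.exons):
                lines.append(
                    f"{chrom}\t.\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
                )
            # phase for a clean ORF starting in-frame
            cds_iter = t.cds_segments if strand == "+" else t.cds_segments[::-1]
            done = 0
            for i, (s, e) in enumerate(cds_iter):
                phase = (3 - done % 3) % 3
                lines.append(
                    f"{chrom}\t.\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{phase}\t"
                    f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}"
                )
                done += e - s
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike, reference: dict[str, str]) -> GeneModelSet:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    transcripts: list[Transcript] = []
    for mrna in db.features_of_type("mRNA"):
        exons = tuple(
            sorted(
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="exon")
            )
        )
        cds = tuple(
            sorted(
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="CDS")
            )
        )
        if not cds:
            continue
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        transcripts.append(
            Transcript(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons if exons else cds,
                cds_segments=cds,
            )
        )
    return GeneModelSet(transcripts, reference)


# ---------------------------------------------------------------- VCF

def write_vcf(
    matrix: GenotypeMatrix,
    path: str | os.PathLike,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    ref = matrix.sites["ref"].to_numpy()
    alt = matrix.sites["alt"].to_numpy()
    for i in range(matrix.n_sites):
        gts = "\t".join(_GT_STRINGS[int(c)] for c in matrix.calls[i])
        lines.append(
            f"{chroms[i]}\t{pos[i]}\t.\t{ref[i]}\t{alt[i]}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    calls = []
    for rec in vcf:
        if not rec.ALT:
            continue
        # multi-allelic records are split into biallelic ones; genotypes
        # carrying another alternate allele become missing for this one
        for ai, alt in enumerate(rec.ALT):
            gt = np.asarray(rec.gt_types, dtype=np.int8)
            codes = np.where(gt == 3, MISSING, gt)
            if len(rec.ALT) > 1:
                per_sample = rec.genotypes  # [a0, a1, phased]
                codes = np.empty(len(samples), dtype=np.int8)
                want = ai + 1
                for si, g in enumerate(per_sample):
                    a = [x for x in g[:-1] if x is not None and x >= 0]
                    if len(a) < 2:
                        codes[si] = MISSING
                    elif any(x not in (0, want) for x in a):
                        codes[si] = MISSING
                    else:
                        codes[si] = {0: HOM_REF, 1: HET, 2: HOM_ALT}[
                            sum(1 for x in a if x == want)
                        ]
            rows.append((rec.CHROM, rec.POS, rec.REF, alt))
            calls.append(codes)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    matrix = np.array(calls, dtype=np.int8) if calls else np.empty((0, len(samples)), np.int8)
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(samples=samples, sites=sites, calls=matrix[order])


# ---------------------------------------------------------------- TSV

def write_genotype_tsv(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Long-format genotype table: sample, chrom, pos, code."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos\tcode\n")
        for si, sample in enumerate(matrix.samples):
            for i in range(matrix.n_sites):
                fh.write(
                    f"{sample}\t{matrix.sites['chrom'].iat[i]}\t"
                    f"{matrix.sites['pos'].iat[i]}\t{int(matrix.calls[i, si])}\n"
                )


def read_genotype_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    samples = sorted(df["sample"].unique())
    sites = (
        df[["chrom", "pos"]]
        .drop_duplicates()
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    sites["ref"] = "N"
    sites["alt"] = "."
    site_idx = {
        (c, p): i for i, (c, p) in enumerate(zip(sites["chrom"], sites["pos"]))
    }
    sample_idx = {s: i for i, s in enumerate(samples)}
    calls = np.full((len(sites), len(samples)), MISSING, dtype=np.int8)
    for sample, chrom, pos, code in df.itertuples(index=False):
        calls[site_idx[(chrom, pos)], sample_idx[sample]] = code
    # drop placeholder alleles so VariantRecord construction is not attempted
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


def write_roh_tsv(blocks: list[RohBlock], path: str | os.PathLike) -> None:
    """PLINK ``.hom``-style table: IID, CHR, BP1, BP2, NSNP, KB."""
    blocks = sorted(blocks, key=lambda b: (b.sample, b.chrom, b.start_bp))
    with open(path, "w") as fh:
        fh.write("IID\tCHR\tBP1\tBP2\tNSNP\tKB\n")
        for b in blocks:
            fh.write(
                f"{b.sample}\t{b.chrom}\t{b.start_bp}\t{b.end_bp}\t"
                f"{b.n_snps}\t{b.length_bp / 1000:.3f}\n"
            )


def read_roh_tsv(path: str | os.PathLike) -> list[RohBlock]:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    return [
        RohBlock(
            sample=str(r.IID),
            chrom=r.CHR,
            start_bp=int(r.BP1),
            end_bp=int(r.BP2),
            n_snps=int(r.NSNP),
        )
        for r in df.itertuples(index=False)
    ]


def write_ancestral_tsv(
    ancestral: dict[tuple[str, int], str], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tallele\n")
        for (chrom, pos), allele in sorted(ancestral.items()):
            fh.write(f"{chrom}\t{pos}\t{allele}\n")


def read_ancestral_tsv(path: str | os.PathLike) -> dict[tuple[str, int], str]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {(r.chrom, int(r.pos)): r.allele for r in df.itertuples(index=False)}


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One gene id per line (first column of a TSV; header optional)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        tok = line.split("\t")[0].strip()
        if tok and tok.lower() not in ("gene", "gene_id"):
            genes.append(tok)
    return genes
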