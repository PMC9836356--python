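"""Readers and writers for the plain-text formats the pipeline exchanges.

VCF is read through cyvcf2; GT-only biallelic VCF v4.2 output is emitted
directly.  Pedigree / truth / haplotype tables are TSV.  BED output is
0-based half-open; everything in memory stays 1-based.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import GenomeLayout, GenotypeMatrix, Pedigree

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(geno: GenotypeMatrix, path: str, layout: GenomeLayout | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gametemap\n")
        if layout is not None:
            for name, length in zip(layout.chrom_names, layout.chrom_lengths_bp):
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.samples) + "\n")
        m = geno.markers
        chroms = m["chrom"].to_numpy()
        pos = m["pos"].to_numpy()
        ref = m["ref"].to_numpy()
        alt = m["alt"].to_numpy()
        for j in range(geno.n_markers):
            gts = "\t".join(_GT[int(d)] for d in geno.dosage[:, j])
            fh.write(f"{chroms[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Load a biallelic GT-only VCF into a GenotypeMatrix (cyvcf2 backend)."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2, 3=missing
        gt[gt == 3] = -1
        dosages.append(gt)
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = np.vstack(dosages).T if dosages else np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(samples, markers, dosage)


def write_pedigree(ped: Pedigree, path: str) -> None:
    ped.table[["offspring", "mother", "father"]].to_csv(path, sep="\t", index=False)


def read_pedigree(path: str) -> Pedigree:
    return Pedigree(pd.read_csv(path, sep="\t", dtype=str))


def write_truth(truth_table: pd.DataFrame, path: str) -> None:
    """Truth TSV: gamete_id, parent_id, chrom, breakpoint_bp (one row per CO)."""
    truth_table.to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(seqs: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(features: pd.DataFrame, path: str) -> None:
    """features columns: chrom, start, end (1-based inclusive), feature_id."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in features.itertuples(index=False):
            attrs = f"ID={r.feature_id}"
            fh.write(
                f"{r.chrom}\tgametemap\tgene\t{r.start}\t{r.end}\t.\t+\t.\t{attrs}\n"
            )


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    """intervals columns: chrom, start0, end0 (0-based half-open), name."""
    intervals.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df
    df.columns = ["chrom", "start0", "end0", "name"][: df.shape[1]]
    return df


def write_haplotypes_tsv(haps, path: str) -> None:
    haps.to_frame().to_csv(path, sep="\t", index=False)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
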