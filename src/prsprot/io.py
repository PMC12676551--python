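"""Readers and writers for the pipeline's on-disk formats.

TSV matrices carry sample IDs in the first column and variant/analyte IDs
in the header. Genotypes may alternatively arrive as VCF 4.x with a DS
(dosage) FORMAT field, falling back to summed GT alleles. Scoring files
follow PGS-catalog column naming.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypePanel, PrsModel, ProteinPanel

FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------- genotypes

def write_genotype_tsv(matrix_path, map_path, geno: GenotypePanel) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.sample_id, columns=geno.snp_id)
    df.index.name = "sample_id"
    df.to_csv(matrix_path, sep="\t", float_format=FLOAT_FMT)
    snp_map = pd.DataFrame({
        "snp_id": geno.snp_id, "chrom": geno.chrom, "pos": geno.pos,
        "effect_allele": geno.effect_allele,
    })
    snp_map.to_csv(map_path, sep="\t", index=False)


def read_genotype_tsv(matrix_path, map_path) -> GenotypePanel:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    snp_map = snp_map.set_index("snp_id").loc[df.columns]
    return GenotypePanel(
        dosages=df.to_numpy(float), snp_id=list(df.columns),
        chrom=list(snp_map["chrom"]), pos=snp_map["pos"].to_numpy(),
        effect_allele=list(snp_map["effect_allele"]),
        sample_id=list(df.index.astype(str)),
    )


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT (effect) allele">
"""

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def write_vcf(path, geno: GenotypePanel) -> None:
    """Plain-text VCF with GT (rounded) and DS carrying the exact dosage.

    The effect allele is written as ALT so that DS counts effect alleles;
    REF is an arbitrary non-complementary other allele.
    """
    order = np.lexsort((geno.pos, np.array(geno.chrom)))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in sorted(set(geno.chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_id) + "\n")
        for j in order:
            alt = geno.effect_allele[j]
            ref = "A" if alt not in ("A", "T") else "C"
            fields = [geno.chrom[j], str(geno.pos[j]), geno.snp_id[j],
                      ref, alt, ".", "PASS", ".", "GT:DS"]
            col = geno.dosages[:, j]
            gt = np.clip(np.rint(col), 0, 2).astype(int)
            gt_str = np.array(["0/0", "0/1", "1/1"])[gt]
            samples = [f"{g}:{FLOAT_FMT % d}" for g, d in zip(gt_str, col)]
            fh.write("\t".join(fields + samples) + "\n")


def read_vcf(path) -> GenotypePanel:
    """Read dosages from a VCF via cyvcf2, preferring DS over GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_id = list(vcf.samples)
    snp_id, chrom, pos, effect_allele, cols = [], [], [], [], []
    for var in vcf:
        snp_id.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        effect_allele.append(var.ALT[0])
        ds = var.format("DS")
        if ds is not None:
            cols.append(np.asarray(ds, dtype=float).ravel())
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            cols.append(np.clip(gts, 0, 1).sum(axis=1).astype(float))
    vcf.close()
    return GenotypePanel(dosages=np.column_stack(cols), snp_id=snp_id,
                         chrom=chrom, pos=np.asarray(pos),
                         effect_allele=effect_allele, sample_id=sample_id)


def read_genotypes(path, map_path=None) -> GenotypePanel:
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    if map_path is None:
        raise ValueError("TSV genotypes require a SNP map path")
    return read_genotype_tsv(path, map_path)


# ------------------------------------------------------------- scoring file

def write_scoring_file(path, model: PrsModel) -> None:
    # weights must round-trip exactly, hence shortest-repr precision
    model.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scoring_file(path) -> PrsModel:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chr_name": str},
                     float_precision="round_trip")
    return PrsModel(snp_id=list(df["rsID"]), chrom=list(df["chr_name"]),
                    pos=df["chr_position"].to_numpy(),
                    effect_allele=list(df["effect_allele"]),
                    weight=df["effect_weight"].to_numpy(float))


# ----------------------------------------------------------------- proteins

def write_protein_tsv(matrix_path, map_path, panel: ProteinPanel) -> None:
    df = pd.DataFrame(panel.abundances, index=panel.sample_id,
                      columns=panel.analyte_id)
    df.index.name = "sample_id"
    df.to_csv(matrix_path, sep="\t", float_format=FLOAT_FMT)
    amap = pd.DataFrame({
        "analyte_id": panel.analyte_id, "gene_symbol": panel.gene_symbol,
        "tss_chrom": panel.tss_chrom, "tss_pos": panel.tss_pos,
    })
    amap.to_csv(map_path, sep="\t", index=False)


def read_protein_tsv(matrix_path, map_path) -> ProteinPanel:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    amap = pd.read_csv(map_path, sep="\t", dtype={"tss_chrom": str})
    amap = amap.set_index("analyte_id").loc[df.columns]
    return ProteinPanel(
        abundances=df.to_numpy(float), analyte_id=list(df.columns),
        gene_symbol=list(amap["gene_symbol"]),
        tss_chrom=list(amap["tss_chrom"]),
        tss_pos=amap["tss_pos"].to_numpy(),
        sample_id=list(df.index.astype(str)),
    )


def write_adjusted_tsv(path, adjusted) -> None:
    df = pd.DataFrame(adjusted.values, index=adjusted.sample_id,
                      columns=adjusted.analyte_id)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


# ------------------------------------------------- covariates / annotations

def write_covariates(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_list(path, genes) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_ceres(path, df: pd.DataFrame) -> None:
    out = df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_ceres(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
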