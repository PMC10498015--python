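"""Genotype input/output: VCF and tabular dosage matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import GenotypeInputError
from .gwas import GenotypeMatrix, SNP_COLUMNS

__all__ = ["read_vcf", "read_dosage_tsv", "write_dosage_tsv", "write_vcf"]


def read_vcf(path: str) -> GenotypeMatrix:
    """Load biallelic sites from a VCF into a dosage matrix.

    Dosage counts copies of the ALT allele from the GT field; missing
    genotypes become NaN.  Multi-allelic sites are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    accessions = list(vcf.samples)
    rows = []
    dosage_cols = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows.append({"snp_id": sid, "chrom": str(var.CHROM), "pos": int(var.POS),
                     "ref": var.REF, "alt": var.ALT[0]})
        gt = np.asarray(var.gt_types)  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        d = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        dosage_cols.append(d)
    if not rows:
        raise GenotypeInputError(f"no biallelic sites found in {path}")
    snps = pd.DataFrame(rows)
    dosages = np.column_stack(dosage_cols)
    return GenotypeMatrix(accessions, snps, dosages)


def read_dosage_tsv(dosage_path: str, snp_map_path: str) -> GenotypeMatrix:
    """Load a dosage TSV (rows = accessions, columns = SNP ids) plus a SNP
    map TSV with columns ``snp_id, chrom, pos``."""
    dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
    snp_map = pd.read_csv(snp_map_path, sep="\t")
    missing = set(SNP_COLUMNS) - set(snp_map.columns)
    if missing:
        raise GenotypeInputError(f"SNP map lacks columns: {sorted(missing)}")
    snp_map = snp_map.set_index("snp_id").loc[list(dos.columns)].reset_index()
    snp_map["chrom"] = snp_map["chrom"].astype(str)
    return GenotypeMatrix(
        [str(a) for a in dos.index],
        snp_map[["snp_id", "chrom", "pos"]],
        dos.to_numpy(dtype=float),
    )


def write_dosage_tsv(G: GenotypeMatrix, dosage_path: str, snp_map_path: str) -> None:
    pd.DataFrame(
        G.dosages, index=pd.Index(G.accessions, name="accession"), columns=G.snps["snp_id"]
    ).to_csv(dosage_path, sep="\t")
    G.snps[["snp_id", "chrom", "pos"]].to_csv(snp_map_path, sep="\t", index=False)


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write dosages as an uncompressed VCF 4.2 with unphased GT calls.

    Dosage 1 is emitted as 0/1; fractional (imputed) dosages are rounded
    to the nearest integer call; NaN becomes ./. .
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    chroms = list(dict.fromkeys(G.snps["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=phtmap\n")
        for c in chroms:
            max_pos = int(G.snps.loc[G.snps["chrom"].astype(str) == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={max_pos + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.accessions) + "\n")
        ref = G.snps["ref"] if "ref" in G.snps.columns else pd.Series("A", index=G.snps.index)
        alt = G.snps["alt"] if "alt" in G.snps.columns else pd.Series("T", index=G.snps.index)
        for j, row in G.snps.iterrows():
            calls = []
            for d in G.dosages[:, j]:
                calls.append("./." if np.isnan(d) else gt_map[int(round(d))])
            fields = [
                str(row["chrom"]), str(int(row["pos"])), str(row["snp_id"]),
                str(ref.loc[j]), str(alt.loc[j]), ".", "PASS", ".", "GT",
            ] + calls
            fh.write("\t".join(fields) + "\n")
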