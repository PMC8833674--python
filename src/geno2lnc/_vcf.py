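"""Plain-text VCF v4.2 (GT-only) writing and reading.

Reading is backed by cyvcf2; writing emits minimal GT-only records so the
round trip ``write_vcf -> read_vcf`` reproduces the in-memory dosage matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from geno2lnc.datatypes import DataError, GenotypeMatrix

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a GT-only VCF v4.2; missing dosages become ``./.``."""
    info = geno.snp_info
    samples = list(map(str, geno.sample_ids))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(info["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        dos = geno.dosages.to_numpy(dtype=float)
        for j, snp in enumerate(geno.snp_ids):
            row = info.loc[snp]
            calls = "\t".join(
                "./." if np.isnan(d) else _GT[d] for d in dos[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP hard genotypes into an ALT-dosage matrix."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages, ids, rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise DataError(f"variant {var.ID} is not biallelic")
        gts = np.array([g[:2] for g in var.genotypes], dtype=float)
        gts[gts < 0] = np.nan
        dosages.append(gts.sum(axis=1))
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        ids.append(snp_id)
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    if not ids:
        raise DataError(f"no variants in {path}")
    dosage_df = pd.DataFrame(
        np.array(dosages).T, index=pd.Index(samples, name="sample_id"), columns=ids
    )
    info = pd.DataFrame(rows, index=ids, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(dosage_df, info)
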