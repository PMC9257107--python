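"""Readers and writers for the package's on-disk formats.

Phased genotypes travel as plain-text VCF 4.2 with phased GT fields
("0|1"); phenotypes and marker maps as TSV (NA = missing); kernels as TSV
with an id header (plus a GCTA-style triplet export for interoperability).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MarkerMap, PhasedGenotypes, PhenotypeTable
from .kernels import RelationshipMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "write_map",
    "read_map",
    "write_kernel",
    "read_kernel",
    "write_kernel_gcta",
]


def write_vcf(geno: PhasedGenotypes, path: str | os.PathLike) -> None:
    """Write phased genotypes as uncompressed VCF 4.2 (GT only)."""
    mmap = geno.map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tracegp\n")
        for c in mmap.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.ids)
            + "\n"
        )
        a = geno.alleles
        miss = geno.missing
        for j in range(geno.m):
            gts = [f"{a[i, j, 0]}|{a[i, j, 1]}" for i in range(geno.n)]
            if miss is not None:
                for i in np.flatnonzero(miss[:, j]):
                    gts[i] = ".|."
            fh.write(
                f"{mmap.chrom[j]}\t{mmap.pos_bp[j]}\t{mmap.snp_ids[j]}"
                f"\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | os.PathLike, require_phased: bool = False) -> PhasedGenotypes:
    """Read a biallelic-SNP VCF into :class:`PhasedGenotypes` via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows = []
    allele_rows = []
    missing_rows = []
    any_unphased = False
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        rows.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS))
        g = np.array([(gt[0], gt[1], gt[2]) for gt in var.genotypes], dtype=int)
        a = g[:, :2]
        miss = (a < 0).any(axis=1)
        if (~g[:, 2].astype(bool) & ~miss).any():
            any_unphased = True
        allele_rows.append(np.clip(a, 0, 1).astype(np.uint8))
        missing_rows.append(miss)
    if not rows:
        raise ValueError("VCF contains no variants")
    if require_phased and any_unphased:
        raise ValueError("unphased genotypes: haplotype models need phased GT")
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp"])
    try:
        df["chrom"] = df["chrom"].astype(int)
    except ValueError:
        pass
    alleles = np.stack(allele_rows, axis=1)  # (n, m, 2)
    missing = np.stack(missing_rows, axis=1)
    return PhasedGenotypes(
        alleles=alleles,
        map=MarkerMap(df),
        ids=ids,
        missing=missing if missing.any() else None,
    )


def write_phenotypes(pheno: PhenotypeTable, path: str | os.PathLike) -> None:
    df = pheno.values.copy()
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col="id", na_values=["NA"])
    return PhenotypeTable(df)


def write_map(mmap: MarkerMap, path: str | os.PathLike) -> None:
    mmap.table.to_csv(path, sep="\t", index=False)


def read_map(path: str | os.PathLike) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t"))


def write_kernel(K: RelationshipMatrix, ids: list[str], path: str | os.PathLike) -> None:
    pd.DataFrame(K.values, index=ids, columns=ids).to_csv(path, sep="\t")


def read_kernel(path: str | os.PathLike, kind: str = "additive") -> tuple[RelationshipMatrix, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(df.to_numpy(), kind), list(df.index)


def write_kernel_gcta(
    K: RelationshipMatrix, ids: list[str], prefix: str | os.PathLike
) -> None:
    """GCTA-GRM-style text triplets: <prefix>.grm.gz-less plain TSV
    (i, j, n_markers, value, 1-based lower triangle) plus <prefix>.grm.id."""
    prefix = Path(prefix)
    m = K.source.get("m", 0)
    with open(f"{prefix}.grm.txt", "w") as fh:
        for i in range(K.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{m}\t{K.values[i, j]:.6g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in ids:
            fh.write(f"{s}\t{s}\n")
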