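"""Core in-memory containers shared across the package.

The three primary objects mirror what a genomic-prediction analysis needs:
a marker map (where each SNP sits), phased genotypes (two haploid allele
codes per individual per SNP, with a derived 0/1/2 dosage view), and a
phenotype table whose missingness mask is the object the cross-validation
schemes manipulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MarkerMap", "PhasedGenotypes", "PhenotypeTable"]


@dataclass
class MarkerMap:
    """Marker map: one row per SNP with chromosome and bp position.

    Positions must be strictly increasing within each chromosome and SNP
    identifiers unique; both are validated on construction.
    """

    table: pd.DataFrame  # columns: snp_id, chrom, pos_bp

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos_bp"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        if self.table["snp_id"].duplicated().any():
            dup = self.table["snp_id"][self.table["snp_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate snp_id in marker map: {dup!r}")
        if (self.table["pos_bp"] < 0).any():
            raise ValueError("negative bp position in marker map")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    def chromosomes(self) -> list:
        """Chromosome labels in map order."""
        return list(dict.fromkeys(self.table["chrom"].tolist()))

    def chrom_indices(self, chrom) -> np.ndarray:
        """Integer indices (into the full map) of the SNPs on one chromosome."""
        return np.flatnonzero(self.table["chrom"].to_numpy() == chrom)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(self.table.iloc[idx].reset_index(drop=True))


@dataclass
class PhasedGenotypes:
    """Phased diploid genotypes for n individuals at m biallelic SNPs.

    ``alleles`` holds the two haploid codes (0/1) per individual and SNP;
    ``dosage`` is the derived alternate-allele count in {0,1,2}. An optional
    boolean ``missing`` mask (n x m) marks sporadically missing genotype
    calls (the simulator never emits these, but QC must handle them).
    """

    alleles: np.ndarray  # (n, m, 2) uint8
    map: MarkerMap
    ids: list[str]
    missing: np.ndarray | None = None  # (n, m) bool

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n, m, 2)")
        if self.alleles.shape[1] != len(self.map):
            raise ValueError("alleles and marker map disagree on SNP count")
        if len(self.ids) != self.alleles.shape[0]:
            raise ValueError("ids and alleles disagree on individual count")
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.alleles.shape[:2]:
                raise ValueError("missing mask must have shape (n, m)")

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def m(self) -> int:
        return self.alleles.shape[1]

    @property
    def dosage(self) -> np.ndarray:
        """Alternate-allele dosage in {0,1,2}; missing entries are np.nan."""
        d = self.alleles.sum(axis=2).astype(float)
        if self.missing is not None:
            d = d.copy()
            d[self.missing] = np.nan
        return d

    def dosage_imputed(self) -> np.ndarray:
        """Dosage with missing entries mean-imputed per SNP."""
        d = self.dosage
        if self.missing is None or not self.missing.any():
            return d
        col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.nonzero(np.isnan(d))
        d[nan_r, nan_c] = col_mean[nan_c]
        return d

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP (missing calls excluded)."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        if self.missing is None:
            return np.ones(self.m)
        return 1.0 - self.missing.mean(axis=0)

    def subset_markers(self, idx: np.ndarray) -> "PhasedGenotypes":
        idx = np.asarray(idx)
        return PhasedGenotypes(
            alleles=self.alleles[:, idx, :],
            map=self.map.subset(idx),
            ids=list(self.ids),
            missing=None if self.missing is None else self.missing[:, idx],
        )

    def subset_individuals(self, idx: np.ndarray) -> "PhasedGenotypes":
        idx = np.asarray(idx)
        return PhasedGenotypes(
            alleles=self.alleles[idx],
            map=self.map,
            ids=[self.ids[i] for i in idx],
            missing=None if self.missing is None else self.missing[idx],
        )


@dataclass
class PhenotypeTable:
    """n x t phenotype values with NaN marking missing cells.

    Rows are individuals (index = id), columns are traits. The CV masking
    schemes operate by copying the table and setting cells to NaN.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def t(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed mask (True = observed)."""
        return self.values.notna()

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(self.values.copy())

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def align_phenotypes(
    geno: PhasedGenotypes, pheno: PhenotypeTable
) -> tuple[PhasedGenotypes, PhenotypeTable, int]:
    """Inner-join genotypes and phenotypes on individual id.

    Returns the aligned pair plus the number of ids dropped from either side.
    """
    common = [i for i in geno.ids if i in set(pheno.ids)]
    dropped = (len(geno.ids) - len(common)) + (len(pheno.ids) - len(common))
    if not common:
        raise ValueError("no shared individual ids between genotypes and phenotypes")
    gidx = [geno.ids.index(i) for i in common]
    return (
        geno.subset_individuals(np.array(gidx)),
        PhenotypeTable(pheno.values.loc[common]),
        dropped,
    )
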