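"""Genomic relationship kernels.

Three constructions share one normalization convention so their variance
components live on a comparable scale:

- additive GRM ``G = Z Z' / (2 sum p(1-p))`` on centered dosages
  (VanRaden method 1);
- haplotypic relationship matrix ``H`` on centered haplotype-allele counts,
  normalized by ``2 sum q(1-q)`` over haplotype-allele frequencies — the
  direct VanRaden analogue on count columns, which makes H with one-SNP
  windows coincide with G;
- mixed panel kernels concatenating selected-SNP dosage columns with
  merged-block haplotype counts under a single joint normalization.

All kernels are Gram matrices, hence PSD up to round-off; a small
stabilizing ridge is added before any downstream solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .markers import HaplotypeProfile

logger = logging.getLogger(__name__)

__all__ = ["RelationshipMatrix", "additive_grm", "haplotype_hrm", "mixed_panel_kernel"]

RIDGE = 1e-6


@dataclass
class RelationshipMatrix:
    """n x n symmetric PSD kernel with a provenance tag."""

    values: np.ndarray
    kind: str  # 'additive' | 'haplotype' | 'mixed'
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel must be square")
        if not np.isfinite(self.values).all():
            raise ValueError("kernel has non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def regularized(self, ridge: float = RIDGE) -> np.ndarray:
        """Kernel plus the stabilizing ridge used before any solve."""
        return self.values + ridge * np.eye(self.n)

    def subset(self, idx: np.ndarray) -> "RelationshipMatrix":
        idx = np.asarray(idx)
        return RelationshipMatrix(
            self.values[np.ix_(idx, idx)], self.kind, dict(self.source)
        )


def _gram(columns: np.ndarray, denom: float, kind: str, source: dict) -> RelationshipMatrix:
    if denom <= 0:
        raise ValueError("kernel normalization constant is zero (no variation)")
    return RelationshipMatrix(columns @ columns.T / denom, kind, source)


def additive_grm(dosage: np.ndarray) -> RelationshipMatrix:
    """VanRaden additive GRM from an n x m dosage matrix in [0, 2].

    Monomorphic SNPs are excluded (logged); allele frequencies come from
    the panel itself, so the diagonal averages ~1 under HWE.
    """
    dosage = np.asarray(dosage, dtype=float)
    if dosage.ndim != 2 or dosage.shape[1] < 1:
        raise ValueError("dosage must be n x m with m >= 1")
    p = dosage.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("additive_grm: excluded %d monomorphic SNPs", n_mono)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; GRM undefined")
    Z = dosage[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    return _gram(Z, denom, "additive", {"m": int(poly.sum())})


def haplotype_hrm(profiles: HaplotypeProfile) -> RelationshipMatrix:
    """Haplotypic relationship matrix from window haplotype-allele counts.

    Columns are centered counts; the normalization ``2 sum q(1-q)`` runs
    over haplotype-allele frequencies q (column mean / 2). Constant columns
    are dropped.
    """
    W = np.asarray(profiles.counts, dtype=float)
    q = W.mean(axis=0) / 2.0
    keep = (q > 0) & (q < 1)
    if not keep.any():
        raise ValueError("all haplotype-allele columns constant; HRM undefined")
    Wc = W[:, keep] - 2.0 * q[keep]
    denom = 2.0 * float(np.sum(q[keep] * (1.0 - q[keep])))
    L = max((w.length for w in profiles.windows), default=0)
    return _gram(Wc, denom, "haplotype", {"n_windows": len(profiles.windows), "L": L})


def mixed_panel_kernel(
    snp_dosage: np.ndarray | None, blocks: HaplotypeProfile | None
) -> RelationshipMatrix:
    """Joint kernel over singleton-SNP dosages and haplotype-block counts.

    Both column families are centered and pooled under one normalization
    (``2 sum p(1-p)`` over SNPs plus ``2 sum q(1-q)`` over block alleles),
    so the construction reduces to the additive GRM when there are no
    blocks and to the HRM when there are no singleton SNPs.
    """
    cols = []
    denom = 0.0
    n = None
    if snp_dosage is not None and np.size(snp_dosage):
        d = np.asarray(snp_dosage, dtype=float)
        p = d.mean(axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        if poly.any():
            cols.append(d[:, poly] - 2.0 * p[poly])
            denom += 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
            n = d.shape[0]
    if blocks is not None and blocks.counts.size:
        W = np.asarray(blocks.counts, dtype=float)
        q = W.mean(axis=0) / 2.0
        keep = (q > 0) & (q < 1)
        if keep.any():
            cols.append(W[:, keep] - 2.0 * q[keep])
            denom += 2.0 * float(np.sum(q[keep] * (1.0 - q[keep])))
            n = W.shape[0]
    if not cols:
        raise ValueError("empty panel: no polymorphic SNPs or block alleles")
    X = np.column_stack(cols) if len(cols) > 1 else cols[0]
    return _gram(X, denom, "mixed", {"n_cols": X.shape[1]})
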