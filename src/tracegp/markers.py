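"""Marker QC, LD diagnostics, haplotype windowing and genetic diversity.

QC follows the usual panel pipeline: MAF filter, call-rate filter, then
windowed greedy LD pruning. LD is the squared Pearson correlation of
dosage vectors; the decay diagnostic bins r^2 by physical distance and
reports where the (smoothed) mean crosses a cutoff. Haplotype windows cut
each chromosome into consecutive fixed-length blocks whose phased allele
counts feed the haplotypic relationship matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .data import MarkerMap, PhasedGenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeWindow",
    "HaplotypeProfile",
    "filter_markers",
    "pairwise_ld",
    "ld_decay_distance",
    "make_haplotype_windows",
    "haplotype_profiles",
    "diversity_summary",
    "BEYOND_MAX_DIST",
]

BEYOND_MAX_DIST = -1  # sentinel returned when mean r^2 never drops below cutoff


@dataclass
class HaplotypeWindow:
    """One haplotype block: ordered SNP indices (into the full map)."""

    chrom: object
    members: np.ndarray  # ordered integer indices into the map

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=int)
        if len(self.members) < 1:
            raise ValueError("empty haplotype window")

    @property
    def length(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeProfile:
    """Haplotype-allele count matrix: one column per distinct observed
    haplotype allele per window; entries count the individual's matching
    haplotypes (rows sum to 2 within each window)."""

    counts: np.ndarray  # (n, n_alleles) float
    window_of_col: np.ndarray  # (n_alleles,) window index per column
    allele_labels: list[str]  # e.g. '01' for the 2-SNP haplotype 0-1
    windows: list[HaplotypeWindow]


def _dosage_for_qc(geno: PhasedGenotypes) -> np.ndarray:
    return geno.dosage_imputed()


def _r2_matrix(d: np.ndarray) -> np.ndarray:
    """All-pairs r^2 of dosage columns; zero-variance columns give NaN."""
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(d.T)
    return c**2


def filter_markers(
    geno: PhasedGenotypes,
    maf_min: float = 0.05,
    call_rate_min: float = 0.9,
    ld_r2_max: float = 0.01,
    prune_window: int = 50,
    prune_step: int = 5,
) -> PhasedGenotypes:
    """Panel QC: MAF filter, call-rate filter, then windowed LD pruning.

    Pruning is greedy left-to-right: inside a sliding window of
    ``prune_window`` SNPs (advancing by ``prune_step``), the later SNP of
    any retained pair with r^2 > ``ld_r2_max`` is dropped; ties always keep
    the lower map index. Filtering an already-filtered panel is a no-op.
    """
    for name, v in (("maf_min", maf_min), ("call_rate_min", call_rate_min),
                    ("ld_r2_max", ld_r2_max)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")

    keep = np.flatnonzero(geno.maf() >= maf_min)
    if len(keep) == 0:
        raise ValueError("MAF filter removed every SNP")
    sub = geno.subset_markers(keep)

    keep = np.flatnonzero(sub.call_rate() >= call_rate_min)
    if len(keep) == 0:
        raise ValueError("call-rate filter removed every SNP")
    sub = sub.subset_markers(keep)

    d = _dosage_for_qc(sub)
    kept_global: list[int] = []
    for chrom in sub.map.chromosomes():
        cidx = sub.map.chrom_indices(chrom)
        alive = np.ones(len(cidx), dtype=bool)
        start = 0
        while True:
            stop = min(start + prune_window, len(cidx))
            widx = np.arange(start, stop)
            widx = widx[alive[widx]]
            if len(widx) > 1:
                r2 = _r2_matrix(d[:, cidx[widx]])
                for a in range(len(widx)):
                    if not alive[widx[a]]:
                        continue
                    for b in range(a + 1, len(widx)):
                        if alive[widx[b]] and r2[a, b] > ld_r2_max:
                            alive[widx[b]] = False
            if stop >= len(cidx):
                break
            start += prune_step
        kept_global.extend(cidx[alive].tolist())
    if not kept_global:
        raise ValueError("LD pruning removed every SNP")
    return sub.subset_markers(np.sort(kept_global))


def pairwise_ld(geno: PhasedGenotypes, max_dist_bp: int) -> pd.DataFrame:
    """Within-chromosome pairwise r^2 for SNP pairs closer than max_dist_bp.

    Returns a table (snp_i, snp_j, dist_bp, r2). Pairs involving a
    zero-variance SNP are skipped and counted in a log summary.
    """
    d = _dosage_for_qc(geno)
    sd = d.std(axis=0)
    records: list[tuple] = []
    n_skipped = 0
    for chrom in geno.map.chromosomes():
        cidx = geno.map.chrom_indices(chrom)
        pos = geno.map.pos_bp[cidx].astype(np.int64)
        ids = geno.map.snp_ids[cidx]
        dc = d[:, cidx]
        z = dc - dc.mean(axis=0)
        denom = sd[cidx] * np.sqrt(len(z))
        for a in range(len(cidx)):
            hi = np.searchsorted(pos, pos[a] + max_dist_bp, side="right")
            js = np.arange(a + 1, hi)
            if len(js) == 0:
                continue
            if denom[a] == 0:
                n_skipped += len(js)
                continue
            ok = denom[js] > 0
            n_skipped += int((~ok).sum())
            js = js[ok]
            if len(js) == 0:
                continue
            r = (z[:, a] @ z[:, js]) / (denom[a] * denom[js])
            for j, rr in zip(js, r):
                records.append((ids[a], ids[j], int(pos[j] - pos[a]), float(rr**2)))
    if n_skipped:
        logger.info("pairwise_ld: skipped %d pairs with a zero-variance SNP", n_skipped)
    return pd.DataFrame(records, columns=["snp_i", "snp_j", "dist_bp", "r2"])


def ld_decay_distance(
    ld: pd.DataFrame, r2_cutoff: float = 0.1, bin_bp: int = 25_000
) -> float:
    """Distance at which binned mean r^2 drops (and stays) below the cutoff.

    Means are smoothed with a 3-bin running mean; the returned value is the
    midpoint of the first smoothed bin below ``r2_cutoff`` with no later bin
    back above it. Returns :data:`BEYOND_MAX_DIST` if the curve never
    settles below the cutoff.
    """
    if len(ld) == 0:
        raise ValueError("empty LD table")
    bins = (ld["dist_bp"].to_numpy() // bin_bp).astype(int)
    means = pd.Series(ld["r2"].to_numpy()).groupby(bins).mean()
    idx = np.arange(means.index.min(), means.index.max() + 1)
    curve = means.reindex(idx).to_numpy()
    curve = pd.Series(curve).interpolate(limit_direction="both").to_numpy()
    smooth = np.convolve(curve, np.ones(3) / 3.0, mode="same")
    if len(curve) >= 3:  # edges of 'same' convolution average over 2 entries
        smooth[0] = curve[:2].mean()
        smooth[-1] = curve[-2:].mean()
    below = smooth < r2_cutoff
    # require every later bin to stay below as well
    stays = np.logical_and.accumulate(below[::-1])[::-1]
    hits = np.flatnonzero(stays)
    if len(hits) == 0:
        return BEYOND_MAX_DIST
    return float((idx[hits[0]] + 0.5) * bin_bp)


def make_haplotype_windows(mmap: MarkerMap, L: int) -> list[HaplotypeWindow]:
    """Non-overlapping consecutive windows of L SNPs per chromosome.

    A chromosome-end remainder of fewer than L SNPs forms one shorter
    window, so the windows always partition the SNP set.
    """
    if L < 1:
        raise ValueError("window length must be >= 1")
    windows: list[HaplotypeWindow] = []
    for chrom in mmap.chromosomes():
        cidx = mmap.chrom_indices(chrom)
        for start in range(0, len(cidx), L):
            windows.append(HaplotypeWindow(chrom, cidx[start : start + L]))
    return windows


def haplotype_profiles(
    geno: PhasedGenotypes, windows: list[HaplotypeWindow]
) -> HaplotypeProfile:
    """Count each individual's copies (0/1/2) of every observed haplotype
    allele within each window, using the phased alleles."""
    if geno.missing is not None and geno.missing.any():
        raise ValueError(
            "haplotype profiles need fully called phased genotypes; "
            "use dosage-based kernels for panels with missing calls"
        )
    n = geno.n
    cols: list[np.ndarray] = []
    col_window: list[int] = []
    labels: list[str] = []
    for w_i, win in enumerate(windows):
        # pack the window's haplotype as an integer code per haploid genome
        sub = geno.alleles[:, win.members, :].astype(np.int64)  # (n, L, 2)
        weights = 1 << np.arange(win.length - 1, -1, -1, dtype=np.int64)
        codes = np.tensordot(sub, weights, axes=([1], [0]))  # (n, 2)
        flat = codes.reshape(-1)
        alleles = np.unique(flat)
        counts = (flat[:, None] == alleles[None, :]).reshape(n, 2, -1).sum(axis=1)
        for k, a in enumerate(alleles):
            cols.append(counts[:, k].astype(float))
            col_window.append(w_i)
            labels.append(format(int(a), f"0{win.length}b"))
    return HaplotypeProfile(
        counts=np.column_stack(cols),
        window_of_col=np.asarray(col_window),
        allele_labels=labels,
        windows=list(windows),
    )


def diversity_summary(
    geno: PhasedGenotypes, hist_bin_width: float = 0.2
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Pairwise Euclidean distances on dosage rows, normalized to [0, 1].

    Returns (distance matrix, histogram table over bins of width 0.2,
    average-linkage dendrogram leaf order).
    """
    if geno.n < 2:
        raise ValueError("need at least 2 individuals")
    d = _dosage_for_qc(geno)
    dist = pdist(d, metric="euclidean")
    dmax = dist.max()
    norm = dist / dmax if dmax > 0 else dist
    edges = np.arange(0.0, 1.0 + hist_bin_width / 2, hist_bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    counts, _ = np.histogram(norm, bins=edges)
    # the maximum distance belongs to the last bin (np.histogram closes it)
    hist = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
            "fraction": counts / counts.sum(),
        }
    )
    if dmax > 0:
        link = hierarchy.linkage(dist, method="average")
        order = np.asarray(hierarchy.leaves_list(link))
    else:
        order = np.arange(geno.n)
    return squareform(norm), hist, order
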