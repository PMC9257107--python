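"""Training-set GWAS, TA-SNP selection and selective marker panels.

The association scan is a mixed-linear-model GWAS: the null model
y = 1 mu + g + e with g ~ N(0, G sigma_g^2) is fitted once by REML, the
data are whitened with the estimated covariance, and every SNP is tested
by generalized least squares with that fixed covariance (the
population-parameters-previously-determined shortcut). Trait-associated
SNPs (p < 0.01) are pooled with the minimum-p SNP of every 300-kb bin;
chosen SNPs whose neighbours lie within 300 kb are chain-merged into
haplotype blocks, and the resulting genotype + haplotype panel feeds the
mixed kernel.

Panel selection inside cross-validation sees training phenotypes only —
never the held-out fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .crossval import AccuracyResult, CVPlan, MaskSpec, ModelSpec, _fit_cell, _safe_corr, apply_mask
from .data import MarkerMap, PhasedGenotypes, PhenotypeTable
from .kernels import RelationshipMatrix, additive_grm, mixed_panel_kernel
from .markers import HaplotypeWindow, haplotype_profiles
from .mixedmodels import reml_single_trait

logger = logging.getLogger(__name__)

__all__ = [
    "SelectivePanel",
    "mlm_gwas",
    "select_ta_snps",
    "assemble_panel",
    "panel_cv_evaluate",
]


@dataclass
class SelectivePanel:
    """Chosen SNPs partitioned into chained blocks and singletons."""

    singletons: list[str]
    blocks: list[list[str]]  # each >= 2 SNP ids, map-ordered
    bin_table: pd.DataFrame | None = None

    @property
    def size(self) -> int:
        return len(self.singletons) + sum(len(b) for b in self.blocks)


def mlm_gwas(
    y: np.ndarray | pd.Series,
    geno: PhasedGenotypes,
    K: RelationshipMatrix,
) -> pd.DataFrame:
    """Per-SNP mixed-model association scan.

    Returns a table (snp_id, chrom, pos_bp, beta, se, p). The per-SNP test
    re-estimates the residual scale after whitening, so with K = I the
    p-values coincide with textbook simple linear regression (t reference,
    n-2 df). Monomorphic SNPs are skipped.
    """
    if isinstance(y, pd.Series):
        y = y.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("mlm_gwas needs fully observed phenotypes")
    n = len(y)
    if geno.n != n or K.n != n:
        raise ValueError("genotypes, kernel and phenotypes must align")

    Kreg = K.regularized()
    sg2, se2, _, _, _ = reml_single_trait(y, Kreg)
    d, U = np.linalg.eigh(Kreg)
    d = np.clip(d, 1e-10, None)
    w = sg2 * d + se2
    S = (U / np.sqrt(w)).T  # whitening: cov(S y) = I

    yt = S @ y
    ones_t = S @ np.ones(n)
    # residualize on the transformed intercept
    ones_norm2 = ones_t @ ones_t
    yt_r = yt - ones_t * (ones_t @ yt) / ones_norm2

    dosage = geno.dosage_imputed()
    p_alt = dosage.mean(axis=0) / 2.0
    poly = (p_alt > 0) & (p_alt < 1)
    Xt = S @ dosage[:, poly]
    Xt_r = Xt - np.outer(ones_t, (ones_t @ Xt) / ones_norm2)
    xx = np.sum(Xt_r**2, axis=0)
    xy = Xt_r.T @ yt_r
    beta = xy / xx
    rss = np.sum(yt_r**2) - beta * xy
    df = n - 2
    sigma2 = np.clip(rss, 0.0, None) / df
    se = np.sqrt(sigma2 / xx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    n_skip = int((~poly).sum())
    if n_skip:
        logger.info("mlm_gwas: skipped %d monomorphic SNPs", n_skip)
    return pd.DataFrame(
        {
            "snp_id": geno.map.snp_ids[poly],
            "chrom": geno.map.chrom[poly],
            "pos_bp": geno.map.pos_bp[poly],
            "beta": beta,
            "se": se,
            "p": pvals,
        }
    )


def select_ta_snps(
    gwas: pd.DataFrame,
    mmap: MarkerMap,
    p_thresh: float = 0.01,
    bin_bp: int = 300_000,
    only_bins_with_signal: bool = False,
) -> list[str]:
    """Trait-associated SNP selection.

    Union of (a) every SNP with p < ``p_thresh`` and (b) the minimum-p SNP
    of each ``bin_bp`` bin (anchored at position 0 per chromosome). Rule (b)
    as stated picks one SNP from every non-empty bin regardless of p;
    ``only_bins_with_signal=True`` restricts (b) to bins containing at
    least one sub-threshold SNP. Returned ids are in map order.
    """
    g = gwas.copy()
    below = set(g.loc[g["p"] < p_thresh, "snp_id"])
    chosen = set(below)
    g["bin"] = (g["pos_bp"] // bin_bp).astype(int)
    for (_, _), sub in g.groupby(["chrom", "bin"], sort=False):
        if only_bins_with_signal and not (sub["p"] < p_thresh).any():
            continue
        chosen.add(sub.loc[sub["p"].idxmin(), "snp_id"])
    order = {s: i for i, s in enumerate(mmap.snp_ids)}
    return sorted(chosen, key=lambda s: order[s])


def assemble_panel(
    chosen: list[str],
    phased: PhasedGenotypes,
    merge_bp: int = 300_000,
) -> tuple[SelectivePanel, np.ndarray | None, list[HaplotypeWindow]]:
    """Chain-merge chosen SNPs into haplotype blocks and singletons.

    Consecutive chosen SNPs on the same chromosome join one block while
    each adjacent gap is <= ``merge_bp`` (so a chained block may span more
    than ``merge_bp`` end to end). Returns the panel, the singleton dosage
    columns and the block windows (for :func:`tracegp.markers.haplotype_profiles`).
    """
    if not chosen:
        raise ValueError("empty chosen SNP set")
    mmap = phased.map
    order = {s: i for i, s in enumerate(mmap.snp_ids)}
    idx = np.array(sorted((order[s] for s in chosen)))
    chroms = mmap.chrom[idx]
    pos = mmap.pos_bp[idx]

    groups: list[list[int]] = [[int(idx[0])]]
    for a in range(1, len(idx)):
        same = chroms[a] == chroms[a - 1]
        close = (pos[a] - pos[a - 1]) <= merge_bp
        if same and close:
            groups[-1].append(int(idx[a]))
        else:
            groups.append([int(idx[a])])

    singletons = [g[0] for g in groups if len(g) == 1]
    block_groups = [g for g in groups if len(g) > 1]
    panel = SelectivePanel(
        singletons=[mmap.snp_ids[i] for i in singletons],
        blocks=[[mmap.snp_ids[i] for i in g] for g in block_groups],
    )
    dosage = phased.dosage_imputed()[:, singletons] if singletons else None
    windows = [
        HaplotypeWindow(mmap.chrom[g[0]], np.array(g)) for g in block_groups
    ]
    return panel, dosage, windows


def panel_kernel(
    chosen: list[str],
    phased: PhasedGenotypes,
    merge_bp: int = 300_000,
    use_haplotypes: bool = True,
) -> tuple[RelationshipMatrix, SelectivePanel]:
    """Kernel for a selective panel: mixed genotype+haplotype (default) or
    genotype-only on the same chosen SNPs."""
    panel, dosage, windows = assemble_panel(chosen, phased, merge_bp)
    if not use_haplotypes:
        order = {s: i for i, s in enumerate(phased.map.snp_ids)}
        idx = np.array(sorted(order[s] for s in chosen))
        return mixed_panel_kernel(phased.dosage_imputed()[:, idx], None), panel
    profiles = haplotype_profiles(phased, windows) if windows else None
    return mixed_panel_kernel(dosage, profiles), panel


def panel_cv_evaluate(
    geno: PhasedGenotypes,
    Y: PhenotypeTable,
    plan: CVPlan,
    spec: MaskSpec,
    model: ModelSpec,
    p_thresh: float = 0.01,
    bin_bp: int = 300_000,
    merge_bp: int = 300_000,
    use_haplotypes: bool = True,
    only_bins_with_signal: bool = False,
) -> tuple[AccuracyResult, pd.DataFrame]:
    """Selective-panel cross-validation with training-only GWAS.

    Per (repeat, fold): run the MLM GWAS on the training portion's observed
    target phenotypes, select TA-SNPs, assemble the panel, build the panel
    kernel over all individuals (genotypes are known for everyone), fit the
    requested model on the masked phenotypes and predict the test fold.
    Also returns a per-cell panel-size table (mean and coefficient of
    variation are the reported panel statistics).
    """
    y_all = Y.values[spec.target].to_numpy(dtype=float)
    K_full = additive_grm(geno.dosage_imputed())
    accs: list[float] = []
    warns: list[str] = []
    sizes: list[tuple[int, int, int]] = []
    for r in range(plan.n_repeats):
        preds = np.full(Y.n, np.nan)
        for f in range(plan.k_folds):
            test = plan.test_indices(r, f)
            train = np.setdiff1d(np.arange(Y.n), test)
            y_tr = y_all[train]
            keep = ~np.isnan(y_tr)
            tr_obs = train[keep]
            if len(tr_obs) == 0:
                raise ValueError("no observed target phenotypes in training set")
            g_tr = geno.subset_individuals(tr_obs)
            gwas = mlm_gwas(y_all[tr_obs], g_tr, K_full.subset(tr_obs))
            chosen = select_ta_snps(
                gwas, geno.map, p_thresh=p_thresh, bin_bp=bin_bp,
                only_bins_with_signal=only_bins_with_signal,
            )
            K_panel, panel = panel_kernel(
                chosen, geno, merge_bp=merge_bp, use_haplotypes=use_haplotypes
            )
            sizes.append((r, f, panel.size))
            masked = apply_mask(Y, plan, r, f, spec)
            fit = _fit_cell(masked, K_panel, spec, model,
                            seed=plan.seed + 1000 * r + f)
            preds[test] = fit.u[spec.target].to_numpy()[test]
        ok = ~np.isnan(y_all)
        accs.append(_safe_corr(preds[ok], y_all[ok], warns, r))
    acc = AccuracyResult(
        per_repeat=np.asarray(accs),
        model=f"panel-{model.model}" + ("-hap" if use_haplotypes else "-geno"),
        scheme=spec.scheme,
        target=spec.target,
        auxiliaries=spec.auxiliaries,
        warnings=warns,
    )
    size_df = pd.DataFrame(sizes, columns=["repeat", "fold", "panel_size"])
    return acc, size_df
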