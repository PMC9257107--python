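"""Genomic prediction mixed models.

Single-trait GBLUP is fitted either by REML (eigendecomposition of the
kernel reduces the restricted likelihood to a 1-D search in the variance
ratio) or by Gibbs sampling. Multi-trait models share one Gibbs sampler for
the stacked model

    y = mu + u + eps,   u ~ N(0, Psi_u kron K),   eps ~ N(0, Psi_e kron I)

with diagonal residual covariance Psi_e and a genetic covariance Psi_u that
is diagonal (independent traits), unstructured (inverse-Wishart updates) or
factor-analytic Psi_u = Lambda Lambda' + Pi (k latent factors). Missing
phenotype cells are sampled from their full conditionals each sweep; this
data augmentation is what lets observed auxiliary phenotypes of test-set
individuals inform their predictions (the CV2/CV3 conditioning).

BMORS is the two-stage stacking variant: per-trait GBLUP predictions
(out-of-sample within the training portion) are fed to a per-target ridge
regression.

Priors (weakly informative, proper): scaled-inverse-chi-square(df 4, scale
half the phenotypic variance) for scalar variances, inverse-Wishart(df t+2,
scale half the diagonal phenotypic variances) for the unstructured Psi_u,
standard-normal loadings for the factor model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .kernels import RelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "FitResult",
    "fit_st_gblup",
    "fit_mt",
    "fit_bmors",
    "estimate_heritability",
    "genetic_correlation",
    "predict_genetic_values",
    "reml_single_trait",
    "blup_closed_form",
]

_PRIOR_DF = 4.0


@dataclass
class VarianceComponents:
    psi_u: np.ndarray  # t x t genetic covariance
    psi_e: np.ndarray  # (t,) diagonal residual variances

    def __post_init__(self) -> None:
        self.psi_u = np.atleast_2d(np.asarray(self.psi_u, dtype=float))
        self.psi_e = np.atleast_1d(np.asarray(self.psi_e, dtype=float))
        if (np.diag(self.psi_u) < 0).any() or (self.psi_e < 0).any():
            raise ValueError("negative variance component")

    @property
    def h2(self) -> np.ndarray:
        sg = np.diag(self.psi_u)
        return sg / (sg + self.psi_e)


@dataclass
class FitResult:
    """Fitted genomic prediction model.

    ``u`` holds the (posterior/BLUP mean) genetic values for *all*
    individuals passed in, observed or masked. ``samples`` retains the
    post-burn-in draws of the variance components and derived summaries for
    MCMC engines.
    """

    model: str  # 'ST-REML' | 'ST' | 'MT-diag' | 'MT-UN' | 'MT-FA' | 'BMORS'
    ids: list[str]
    traits: list[str]
    mu: np.ndarray
    u: pd.DataFrame  # ids x traits
    vc: VarianceComponents
    iterations: int = 0
    burn_in: int = 0
    seed: int | None = None
    samples: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def h2(self) -> np.ndarray:
        """Per-trait heritability: posterior mean of the per-sweep ratio for
        MCMC fits, plug-in ratio otherwise."""
        if "h2" in self.samples:
            return np.asarray(self.samples["h2"]).mean(axis=0)
        return self.vc.h2


def _check_kernel(K: RelationshipMatrix, n: int) -> np.ndarray:
    if K.n != n:
        raise ValueError(f"kernel dimension {K.n} does not match data ({n})")
    Kr = K.regularized()
    w = np.linalg.eigvalsh(Kr)
    if w.min() < -1e-6:
        raise ValueError(f"kernel not PSD (min eigenvalue {w.min():.3e})")
    return Kr


def reml_single_trait(
    y: np.ndarray, Kreg: np.ndarray
) -> tuple[float, float, float, float, bool]:
    """REML for y = 1 mu + g + e with g ~ N(0, K sigma_g^2).

    Profiles the restricted likelihood down to the ratio
    delta = sigma_e^2 / sigma_g^2 via the eigendecomposition of K and a
    bounded 1-D search on log(delta). Returns
    (sigma_g2, sigma_e2, mu, loglik, converged); a flat likelihood is
    reported with the boundary estimate and converged=False.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    d, U = np.linalg.eigh(Kreg)
    d = np.clip(d, 1e-10, None)
    ys = U.T @ y
    xs = U.T @ np.ones(n)

    def neg_restricted_ll(log_delta: float) -> float:
        w = d + np.exp(log_delta)
        xwx = np.sum(xs**2 / w)
        mu = np.sum(xs * ys / w) / xwx
        r = ys - xs * mu
        rss = np.sum(r**2 / w)
        sg2 = rss / (n - 1)
        return 0.5 * (
            (n - 1) * (1.0 + np.log(2 * np.pi * sg2))
            + np.sum(np.log(w))
            + np.log(xwx)
        )

    lo, hi = -12.0, 12.0
    res = minimize_scalar(neg_restricted_ll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    log_delta = float(res.x)
    converged = bool(res.success) and (lo + 1e-3 < log_delta < hi - 1e-3)
    if not converged:
        logger.warning("REML at or near boundary (log delta = %.2f)", log_delta)
    delta = np.exp(log_delta)
    w = d + delta
    xwx = np.sum(xs**2 / w)
    mu = float(np.sum(xs * ys / w) / xwx)
    rss = float(np.sum((ys - xs * mu) ** 2 / w))
    sg2 = rss / (n - 1)
    se2 = sg2 * delta
    return sg2, se2, mu, -float(res.fun), converged


def fit_st_gblup(
    y: pd.Series | np.ndarray,
    K: RelationshipMatrix,
    engine: str = "reml",
    iterations: int = 2000,
    burn_in: int = 1000,
    seed: int = 0,
    ids: list[str] | None = None,
    trait: str = "y",
) -> FitResult:
    """Single-trait GBLUP with missing phenotypes allowed (NaN).

    The REML engine estimates variance components on the observed subset
    and BLUP-predicts genetic values for everyone; the Gibbs engine runs
    the shared sampler with t=1 (missing values imputed each sweep).
    """
    if isinstance(y, pd.Series):
        ids = list(y.index) if ids is None else ids
        trait = y.name or trait
        y = y.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if ids is None:
        ids = [str(i) for i in range(n)]
    obs = ~np.isnan(y)
    if obs.sum() < 10:
        raise ValueError("need at least 10 observed phenotypes")
    Kreg = _check_kernel(K, n)

    if engine == "gibbs":
        Y = pd.DataFrame(y[:, None], index=ids, columns=[trait])
        fit = fit_mt(
            Y, K, structure="diag", iterations=iterations, burn_in=burn_in, seed=seed
        )
        fit.model = "ST"
        return fit
    if engine != "reml":
        raise ValueError(f"unknown engine {engine!r}")

    oidx = np.flatnonzero(obs)
    Ko = Kreg[np.ix_(oidx, oidx)]
    sg2, se2, mu, ll, converged = reml_single_trait(y[oidx], Ko)
    # BLUP for all individuals: g = sigma_g^2 K[:, obs] V^-1 (y - mu)
    d, U = np.linalg.eigh(Ko)
    d = np.clip(d, 1e-10, None)
    r = U.T @ (y[oidx] - mu)
    alpha = U @ (r / (d + se2 / max(sg2, 1e-12)))  # = sigma_g^2 V^-1 r / sigma_g^2
    g = Kreg[:, oidx] @ alpha
    vc = VarianceComponents(np.array([[sg2]]), np.array([se2]))
    return FitResult(
        model="ST-REML",
        ids=list(ids),
        traits=[trait],
        mu=np.array([mu]),
        u=pd.DataFrame(g[:, None], index=ids, columns=[trait]),
        vc=vc,
        diagnostics={"loglik": ll, "converged": converged},
    )


def _scaled_inv_chi2(rng, df: float, scale_sum: float) -> float:
    return scale_sum / rng.chisquare(df)


def _gibbs_mt(
    Y: np.ndarray,
    Kreg: np.ndarray,
    structure: str,
    k: int,
    iterations: int,
    burn_in: int,
    rng: np.random.Generator,
    fixed: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    n, t = Y.shape
    miss = np.isnan(Y)
    if miss.all(axis=0).any():
        j = int(np.flatnonzero(miss.all(axis=0))[0])
        raise ValueError(f"trait column {j} is entirely missing")

    d, U = np.linalg.eigh(Kreg)
    d = np.clip(d, 1e-10, None)

    col_mean = np.nanmean(Y, axis=0)
    col_var = np.nanvar(Y, axis=0, ddof=1)
    col_var = np.where(col_var > 0, col_var, 1.0)
    Yc = Y.copy()
    Yc[miss] = np.broadcast_to(col_mean, Y.shape)[miss]

    nu0 = _PRIOR_DF
    s0_g = 0.5 * col_var
    s0_e = 0.5 * col_var
    iw_df0 = t + 2.0
    iw_S0 = 0.5 * np.diag(col_var)

    mu = col_mean.copy()
    if fixed is not None:
        Psi_u = np.atleast_2d(np.asarray(fixed[0], dtype=float)).copy()
        psi_e = np.atleast_1d(np.asarray(fixed[1], dtype=float)).copy()
    else:
        Psi_u = np.diag(0.5 * col_var)
        psi_e = 0.5 * col_var
    u = np.zeros((n, t))
    if structure == "fa":
        if fixed is None and t < 3:
            raise ValueError("factor-analytic structure needs at least 3 traits")
        k = max(1, min(k, t - 1))
        Lam = 0.1 * rng.standard_normal((t, k))
        Pi = 0.5 * col_var.copy()

    n_jitter = 0
    kept = iterations - burn_in
    u_mean = np.zeros((n, t))
    mu_mean = np.zeros(t)
    psi_u_samp = np.zeros((kept, t, t))
    psi_e_samp = np.zeros((kept, t))
    h2_samp = np.zeros((kept, t))
    cor_samp = np.zeros((kept, t, t))
    u_samp_sq = np.zeros((n, t))

    eye_t = np.eye(t)
    for sweep in range(iterations):
        # 1. impute missing cells from their full conditional
        if miss.any():
            draw = mu + u + rng.standard_normal((n, t)) * np.sqrt(psi_e)
            Yc[miss] = draw[miss]

        # 2. genetic values in the kernel eigenbasis (t x t solve per eigenpair)
        R = U.T @ (Yc - mu)
        Psi_u_inv = np.linalg.inv(Psi_u + 1e-10 * eye_t)
        A = Psi_u_inv[None, :, :] / d[:, None, None] + np.diag(1.0 / psi_e)[None, :, :]
        b = (R / psi_e)[:, :, None]
        mean = np.linalg.solve(A, b)
        L = np.linalg.cholesky(A)
        z = rng.standard_normal((n, t, 1))
        u_rot = (mean + np.linalg.solve(A, L @ z))[:, :, 0]
        u = U @ u_rot

        # 3. intercepts (flat prior)
        resid0 = Yc - u
        mu = resid0.mean(axis=0) + rng.standard_normal(t) * np.sqrt(psi_e / n)

        # 4. genetic covariance
        S = (u_rot / d[:, None]).T @ u_rot
        if fixed is None:
            if structure == "diag":
                Psi_u = np.diag(
                    [
                        _scaled_inv_chi2(rng, nu0 + n, nu0 * s0_g[j] + S[j, j])
                        for j in range(t)
                    ]
                )
            elif structure == "un":
                scale = iw_S0 + S
                for _ in range(10):
                    try:
                        Psi_u = stats.invwishart.rvs(
                            df=iw_df0 + n, scale=scale, random_state=rng
                        )
                        Psi_u = np.atleast_2d(Psi_u)
                        np.linalg.cholesky(Psi_u + 1e-12 * eye_t)
                        break
                    except np.linalg.LinAlgError:
                        n_jitter += 1
                        scale = scale + 1e-8 * eye_t
            elif structure == "fa":
                # latent scores: mean shared across eigenpairs, covariance d_i M^-1
                Pi_inv_Lam = Lam / Pi[:, None]
                M = Lam.T @ Pi_inv_Lam + np.eye(k)
                Minv = np.linalg.inv(M)
                F_mean = u_rot @ Pi_inv_Lam @ Minv.T
                Lm = np.linalg.cholesky(Minv)
                F = F_mean + (rng.standard_normal((n, k)) @ Lm.T) * np.sqrt(d)[:, None]
                # loadings row by row (weighted regression, N(0,1) prior)
                Fw = F / d[:, None]
                FtDF = F.T @ Fw
                for j in range(t):
                    prec = FtDF / Pi[j] + np.eye(k)
                    cov = np.linalg.inv(prec)
                    mean_l = cov @ (Fw.T @ u_rot[:, j]) / Pi[j]
                    Lam[j] = mean_l + np.linalg.cholesky(cov) @ rng.standard_normal(k)
                # uniquenesses
                E = u_rot - F @ Lam.T
                for j in range(t):
                    ss = np.sum(E[:, j] ** 2 / d)
                    Pi[j] = _scaled_inv_chi2(rng, nu0 + n, nu0 * 0.5 * s0_g[j] + ss)
                Psi_u = Lam @ Lam.T + np.diag(Pi)
            else:
                raise ValueError(f"unknown structure {structure!r}")

        # 5. residual variances (diagonal)
        if fixed is None:
            resid = resid0 - mu
            sse = np.sum(resid**2, axis=0)
            psi_e = np.array(
                [
                    _scaled_inv_chi2(rng, nu0 + n, nu0 * s0_e[j] + sse[j])
                    for j in range(t)
                ]
            )

        if sweep >= burn_in:
            i = sweep - burn_in
            u_mean += u
            u_samp_sq += u**2
            mu_mean += mu
            psi_u_samp[i] = Psi_u
            psi_e_samp[i] = psi_e
            sg = np.diag(Psi_u)
            h2_samp[i] = sg / (sg + psi_e)
            sd = np.sqrt(np.clip(sg, 1e-12, None))
            cor_samp[i] = Psi_u / np.outer(sd, sd)

    return {
        "u_mean": u_mean / kept,
        "u_var": u_samp_sq / kept - (u_mean / kept) ** 2,
        "mu_mean": mu_mean / kept,
        "psi_u": psi_u_samp,
        "psi_e": psi_e_samp,
        "h2": h2_samp,
        "cor": cor_samp,
        "n_jitter": n_jitter,
    }


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial positive sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    v = np.sum(x**2)
    if v == 0 or n < 4:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1 :] / v
    s = 1.0
    for lag in range(1, n // 2):
        pair = acf[2 * lag - 1] + acf[2 * lag] if 2 * lag < n else 0.0
        if pair <= 0:
            break
        s += 2 * pair
    return float(n / s)


def fit_mt(
    Y: pd.DataFrame,
    K: RelationshipMatrix,
    structure: str = "un",
    k: int = 1,
    iterations: int = 20_000,
    burn_in: int = 12_000,
    seed: int = 0,
    fixed_components: tuple[np.ndarray, np.ndarray] | None = None,
) -> FitResult:
    """Multi-trait GBLUP by Gibbs sampling.

    ``structure`` selects the genetic covariance update: 'diag' (independent
    scaled-inverse-chi-square), 'un' (inverse-Wishart) or 'fa'
    (factor-analytic with ``k`` latent factors). The default chain length
    (20,000 sweeps, 12,000 burn-in) matches the analysis profile; pass
    shorter chains for cross-validation work. ``fixed_components`` freezes
    (Psi_u, psi_e) — used for closed-form cross-checks.
    """
    ids = list(Y.index)
    traits = list(Y.columns)
    arr = Y.to_numpy(dtype=float)
    n, t = arr.shape
    if t < 2 and not (structure == "diag"):
        raise ValueError("multi-trait structures need at least 2 traits")
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    Kreg = _check_kernel(K, n)
    rng = np.random.default_rng(seed)
    out = _gibbs_mt(arr, Kreg, structure, k, iterations, burn_in, rng,
                    fixed=fixed_components)
    if out["n_jitter"]:
        logger.info("fit_mt: %d jittered covariance redraws", out["n_jitter"])
    psi_u = out["psi_u"].mean(axis=0)
    psi_e = out["psi_e"].mean(axis=0)
    tag = {"diag": "MT-diag", "un": "MT-UN", "fa": "MT-FA"}[structure]
    if t == 1:
        tag = "ST"
    ess = {tr: _ess(out["h2"][:, j]) for j, tr in enumerate(traits)}
    return FitResult(
        model=tag,
        ids=ids,
        traits=traits,
        mu=out["mu_mean"],
        u=pd.DataFrame(out["u_mean"], index=ids, columns=traits),
        vc=VarianceComponents(psi_u, psi_e),
        iterations=iterations,
        burn_in=burn_in,
        seed=seed,
        samples={"psi_u": out["psi_u"], "psi_e": out["psi_e"],
                 "h2": out["h2"], "cor": out["cor"]},
        diagnostics={"ess_h2": ess, "n_jitter": out["n_jitter"],
                     "u_var": out["u_var"]},
    )


def estimate_heritability(fit: FitResult) -> pd.Series:
    """Per-trait genomic heritability h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
    return pd.Series(fit.h2, index=fit.traits, name="h2")


def genetic_correlation(fit: FitResult) -> pd.DataFrame:
    """Genetic correlation matrix from the posterior-mean Psi_u."""
    t = len(fit.traits)
    if fit.model == "MT-diag" or (fit.samples and fit.model == "ST"):
        if t > 1:
            warnings.warn(
                "diagonal genetic covariance: correlations are identically zero"
            )
        return pd.DataFrame(np.eye(t), index=fit.traits, columns=fit.traits)
    psi = fit.vc.psi_u
    sd = np.sqrt(np.clip(np.diag(psi), 1e-300, None))
    return pd.DataFrame(psi / np.outer(sd, sd), index=fit.traits, columns=fit.traits)


def predict_genetic_values(
    fit: FitResult, target: str, ids: list[str] | None = None
) -> pd.Series:
    """Posterior/BLUP mean genetic value for the target trait.

    Because missing phenotype cells are augmented inside the sampler, these
    predictions already condition on whatever auxiliary phenotypes the
    requested individuals had observed.
    """
    if target not in fit.traits:
        raise KeyError(f"unknown trait {target!r}")
    col = fit.u[target]
    if ids is None:
        return col
    missing = [i for i in ids if i not in fit.u.index]
    if missing:
        raise KeyError(f"unknown individual ids: {missing[:5]}")
    return col.loc[ids]


def blup_closed_form(
    Y: pd.DataFrame,
    K: RelationshipMatrix,
    psi_u: np.ndarray,
    psi_e: np.ndarray,
) -> pd.DataFrame:
    """Closed-form multi-trait BLUP with known variance components.

    Direct dense solve of u = (Psi_u kron K) V^{-1} (y - X mu_GLS) on the
    stacked system; intended as an independent oracle on small n.
    """
    arr = Y.to_numpy(dtype=float)
    n, t = arr.shape
    if np.isnan(arr).any():
        raise ValueError("closed-form BLUP expects complete data")
    Kreg = K.regularized()
    psi_u = np.atleast_2d(psi_u)
    psi_e = np.atleast_1d(psi_e)
    Cu = np.kron(psi_u, Kreg)
    Ce = np.kron(np.diag(psi_e), np.eye(n))
    V = Cu + Ce
    X = np.kron(np.eye(t), np.ones((n, 1)))
    yv = arr.T.reshape(-1)  # trait-major stacking
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    mu = np.linalg.solve(XtVi @ X, XtVi @ yv)
    u = Cu @ (Vi @ (yv - X @ mu))
    return pd.DataFrame(u.reshape(t, n).T, index=Y.index, columns=Y.columns)


def fit_bmors(
    Y: pd.DataFrame,
    K: RelationshipMatrix,
    engine: str = "reml",
    iterations: int = 2000,
    burn_in: int = 1000,
    seed: int = 0,
    inner_folds: int = 5,
    ridge_alpha: float = 1e-3,
    stage2: str = "ridge",
) -> FitResult:
    """Bayesian multi-output regressor stacking (two-stage).

    Stage 1 fits a per-trait GBLUP; predicted values for observed
    individuals come from an internal ``inner_folds``-fold out-of-sample
    split (avoiding stage-2 leakage) and masked individuals are predicted
    from the full observed set. Stage 2 regresses each target's observed
    phenotypes on all t stage-1 prediction columns with a ridge penalty;
    the stage-2 output is the prediction for the target's masked cells.
    """
    ids = list(Y.index)
    traits = list(Y.columns)
    arr = Y.to_numpy(dtype=float)
    n, t = arr.shape
    if t < 2:
        raise ValueError("BMORS needs at least 2 traits")
    rng = np.random.default_rng(seed)

    stage1 = np.zeros((n, t))
    for j in range(t):
        yj = arr[:, j]
        obs = np.flatnonzero(~np.isnan(yj))
        fit_all = fit_st_gblup(
            yj, K, engine=engine, iterations=iterations, burn_in=burn_in,
            seed=seed + j, ids=ids, trait=traits[j],
        )
        pred = fit_all.u.iloc[:, 0].to_numpy().copy()
        # out-of-sample stage-1 values for the observed individuals
        perm = rng.permutation(obs)
        for fold in np.array_split(perm, inner_folds):
            if len(fold) == 0:
                continue
            y_in = yj.copy()
            y_in[fold] = np.nan
            f = fit_st_gblup(
                y_in, K, engine=engine, iterations=iterations, burn_in=burn_in,
                seed=seed + j, ids=ids, trait=traits[j],
            )
            pred[fold] = f.u.iloc[:, 0].to_numpy()[fold]
        stage1[:, j] = pred

    u_out = np.array(stage1)
    betas = np.zeros((t, t))
    if stage2 == "identity":
        # degenerate stacking (unit own-trait coefficient): stage-1 output
        np.fill_diagonal(betas, 1.0)
        vc = VarianceComponents(np.diag(stage1.var(axis=0, ddof=1)), np.ones(t))
        return FitResult(
            model="BMORS", ids=ids, traits=traits, mu=np.zeros(t),
            u=pd.DataFrame(u_out, index=ids, columns=traits), vc=vc, seed=seed,
            diagnostics={"stage2_coefficients": betas,
                         "stage1": pd.DataFrame(stage1, index=ids, columns=traits)},
        )
    for j in range(t):
        obs = ~np.isnan(arr[:, j])
        P = stage1[obs]
        if P.std(axis=0).max() < 1e-12:
            warnings.warn(
                f"degenerate stage-1 predictions for {traits[j]}; "
                "falling back to stage-1 output"
            )
            continue
        Pc = np.column_stack([np.ones(obs.sum()), P])
        A = Pc.T @ Pc + ridge_alpha * np.diag([0.0] + [1.0] * t)
        beta = np.linalg.solve(A, Pc.T @ arr[obs, j])
        betas[j] = beta[1:]
        u_out[:, j] = np.column_stack([np.ones(n), stage1]) @ beta

    vc = VarianceComponents(np.diag(stage1.var(axis=0, ddof=1)), np.ones(t))
    return FitResult(
        model="BMORS",
        ids=ids,
        traits=traits,
        mu=np.zeros(t),
        u=pd.DataFrame(u_out, index=ids, columns=traits),
        vc=vc,
        seed=seed,
        diagnostics={"stage2_coefficients": betas,
                     "stage1": pd.DataFrame(stage1, index=ids, columns=traits)},
    )
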