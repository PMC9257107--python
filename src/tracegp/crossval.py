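"""Cross-validation schemes, accuracy and model comparison.

The three phenotyping designs differ only in which cells of the phenotype
table are visible when a fold is held out (target trait always hidden in
the test fold):

- ST-CV1: auxiliaries hidden everywhere (single-trait baseline);
- MT-CV1: auxiliaries visible in the training folds only;
- MT-CV2: auxiliaries visible in training and test folds;
- MT-CV3: auxiliaries visible in the test fold only.

The protocol is 5 folds x 20 repeats; accuracy per repeat is the Pearson
correlation between predictions pooled over the five test folds and the
observed phenotypes, giving 20 values per cell. Models are compared with a
paired t-test on the per-repeat accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import PhenotypeTable
from .kernels import RelationshipMatrix
from .mixedmodels import FitResult, fit_bmors, fit_mt, fit_st_gblup

__all__ = [
    "CVPlan",
    "MaskSpec",
    "ModelSpec",
    "AccuracyResult",
    "make_cv_plan",
    "apply_mask",
    "evaluate",
    "relative_gain",
    "format_gain",
    "compare_models",
]

SCHEMES = ("ST-CV1", "MT-CV1", "MT-CV2", "MT-CV3")


@dataclass
class CVPlan:
    """Fold assignments: ``folds[r, i]`` is individual i's fold in repeat r."""

    n: int
    k_folds: int
    n_repeats: int
    folds: np.ndarray  # (n_repeats, n) int
    seed: int

    def test_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds[repeat] == fold)


@dataclass
class MaskSpec:
    """Scheme plus trait roles; auxiliaries must not contain the target."""

    scheme: str
    target: str
    auxiliaries: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected {SCHEMES}")
        self.auxiliaries = tuple(self.auxiliaries)
        if self.target in self.auxiliaries:
            raise ValueError("target trait cannot be its own auxiliary")
        if self.scheme != "ST-CV1" and not self.auxiliaries:
            raise ValueError(f"{self.scheme} needs at least one auxiliary trait")


@dataclass
class ModelSpec:
    """Which model to fit in each training/prediction cell."""

    model: str = "st"  # 'st' | 'diag' | 'un' | 'fa' | 'bmors'
    engine: str = "reml"  # for 'st': 'reml' or 'gibbs'
    k: int = 1  # FA latent factors
    iterations: int = 2000
    burn_in: int = 1000


@dataclass
class AccuracyResult:
    """Per-repeat pooled-fold Pearson accuracies for one evaluation cell."""

    per_repeat: np.ndarray
    model: str
    scheme: str
    target: str
    auxiliaries: tuple[str, ...] = ()
    warnings: list[str] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_repeat))


def make_cv_plan(
    n: int, k_folds: int = 5, n_repeats: int = 20, seed: int = 0
) -> CVPlan:
    """Random equal-sized (within one) fold partition per repeat."""
    if n < k_folds:
        raise ValueError("need at least as many individuals as folds")
    rng = np.random.default_rng(seed)
    folds = np.empty((n_repeats, n), dtype=int)
    for r in range(n_repeats):
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, k_folds)):
            folds[r, chunk] = f
    return CVPlan(n=n, k_folds=k_folds, n_repeats=n_repeats, folds=folds, seed=seed)


def apply_mask(
    Y: PhenotypeTable, plan: CVPlan, repeat: int, fold: int, spec: MaskSpec
) -> PhenotypeTable:
    """Phenotype visibility for one (repeat, fold) cell under a scheme."""
    for tr in (spec.target, *spec.auxiliaries):
        if tr not in Y.traits:
            raise KeyError(f"trait {tr!r} not in phenotype table")
    test = plan.test_indices(repeat, fold)
    is_test = np.zeros(Y.n, dtype=bool)
    is_test[test] = True

    out = Y.copy()
    vals = out.values
    vals.iloc[is_test, vals.columns.get_loc(spec.target)] = np.nan
    aux = list(spec.auxiliaries)
    if spec.scheme == "ST-CV1":
        hide_traits = [c for c in Y.traits if c != spec.target]
        vals.loc[:, hide_traits] = np.nan
    elif spec.scheme == "MT-CV1":
        vals.iloc[is_test, [vals.columns.get_loc(a) for a in aux]] = np.nan
        _hide_unused(vals, spec)
    elif spec.scheme == "MT-CV2":
        _hide_unused(vals, spec)
    elif spec.scheme == "MT-CV3":
        vals.iloc[~is_test, [vals.columns.get_loc(a) for a in aux]] = np.nan
        _hide_unused(vals, spec)
    return out


def _hide_unused(vals: pd.DataFrame, spec: MaskSpec) -> None:
    """Traits that are neither target nor auxiliary play no role in the cell."""
    unused = [c for c in vals.columns if c != spec.target and c not in spec.auxiliaries]
    if unused:
        vals.loc[:, unused] = np.nan


def _fit_cell(
    Ymasked: PhenotypeTable,
    K: RelationshipMatrix,
    spec: MaskSpec,
    model: ModelSpec,
    seed: int,
) -> FitResult:
    used = [spec.target, *spec.auxiliaries]
    Ysub = Ymasked.values[used] if model.model != "st" else Ymasked.values[[spec.target]]
    if model.model == "st":
        return fit_st_gblup(
            Ysub[spec.target], K, engine=model.engine,
            iterations=model.iterations, burn_in=model.burn_in, seed=seed,
        )
    if model.model == "bmors":
        return fit_bmors(
            Ysub, K, engine=model.engine, iterations=model.iterations,
            burn_in=model.burn_in, seed=seed,
        )
    return fit_mt(
        Ysub, K, structure=model.model, k=model.k,
        iterations=model.iterations, burn_in=model.burn_in, seed=seed,
    )


def evaluate(
    Y: PhenotypeTable,
    K: RelationshipMatrix,
    model: ModelSpec,
    spec: MaskSpec,
    plan: CVPlan,
    per_fold: bool = False,
) -> AccuracyResult:
    """Run the full CV protocol for one (model, scheme, target) cell.

    For each repeat the five test folds' (prediction, observed phenotype)
    pairs are pooled into a single Pearson correlation (default), or one
    correlation per fold with ``per_fold=True``. Constant predictions in a
    repeat are recorded as accuracy 0 with a warning flag.
    """
    if spec.scheme != "ST-CV1" and model.model == "st":
        raise ValueError("single-trait model is only valid under ST-CV1")
    y_obs = Y.values[spec.target].to_numpy(dtype=float)
    accs: list[float] = []
    warns: list[str] = []
    for r in range(plan.n_repeats):
        preds = np.full(Y.n, np.nan)
        fold_accs: list[float] = []
        for f in range(plan.k_folds):
            test = plan.test_indices(r, f)
            masked = apply_mask(Y, plan, r, f, spec)
            fit = _fit_cell(masked, K, spec, model, seed=plan.seed + 1000 * r + f)
            p = fit.u[spec.target].to_numpy()[test]
            preds[test] = p
            if per_fold:
                fold_accs.append(_safe_corr(p, y_obs[test], warns, r))
        if per_fold:
            accs.extend(fold_accs)
        else:
            ok = ~np.isnan(y_obs)
            accs.append(_safe_corr(preds[ok], y_obs[ok], warns, r))
    return AccuracyResult(
        per_repeat=np.asarray(accs),
        model=model.model,
        scheme=spec.scheme,
        target=spec.target,
        auxiliaries=spec.auxiliaries,
        warnings=warns,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray, warns: list[str], r: int) -> float:
    if np.std(a) < 1e-14 or np.std(b) < 1e-14:
        warns.append(f"repeat {r}: constant predictions, accuracy recorded as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def relative_gain(base: float, improved: float) -> float:
    """Percent change of ``improved`` over ``base``: 100 (improved-base)/base."""
    if base == 0:
        raise ZeroDivisionError("relative gain undefined for a zero baseline")
    return 100.0 * (improved - base) / base


def format_gain(gain: float, decimals: int = 1, mode: str = "round") -> str:
    """Render a percent gain at a given precision.

    ``mode='round'`` is conventional rounding; ``mode='truncate'`` chops
    toward zero (published gain tables mix both conventions).
    """
    if mode == "round":
        v = round(gain, decimals)
    elif mode == "truncate":
        f = 10.0**decimals
        v = np.trunc(gain * f) / f
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return f"{v:.{decimals}f}%" if decimals > 0 else f"{v:.0f}%"


def compare_models(
    a: AccuracyResult, b: AccuracyResult, paired: bool = True
) -> tuple[float, float]:
    """Student t-test on per-repeat accuracies; returns (statistic, p).

    Paired by default (both cells evaluated on the same CV plan); Welch's
    two-sample test via ``paired=False``. Identical vectors give p = 1 with
    a warning instead of a NaN from the zero-variance difference.
    """
    xa, xb = np.asarray(a.per_repeat), np.asarray(b.per_repeat)
    if paired:
        if len(xa) != len(xb):
            raise ValueError("paired comparison needs equal repeat counts")
        diff = xa - xb
        sd = diff.std(ddof=1) if len(diff) > 1 else 0.0
        if sd == 0.0:
            if np.allclose(diff, 0.0):
                warnings.warn("zero accuracy differences; p reported as 1")
                return 0.0, 1.0
            warnings.warn("constant nonzero difference; p reported as 0")
            return float(np.inf * np.sign(diff.mean())), 0.0
        t, p = stats.ttest_rel(xa, xb)
    else:
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return float(t), float(p)
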