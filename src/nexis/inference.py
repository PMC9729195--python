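"""Functional surface over the estimators: the two-stage bootstrap pipeline.

These are thin wrappers for scripted use; the estimator classes in
:mod:`nexis.estimators` are the primary API. The pipeline for real data is

1. ``fit_global``  — multistart fit of (γ, β) [NDM] or (γ, α, β) [global],
   followed by a 100 x 80% region bootstrap for CIs;
2. ``fit_microglia`` — gene model with (γ, α, β) anchored to the global
   bootstrap means/CIs and (p, b) fit free, plus its own bootstrap;
3. ``fisher_compare`` on the bootstrap correlation draws for significance.

``fit_gamma_only`` supports dilution-transfer experiments: all rate
parameters carried over fixed, only the seed rescale γ re-estimated.
"""

from __future__ import annotations

import numpy as np

from .datatypes import Connectome, FitResult, NexisParams, PathologyData
from .estimators import NDM, NexisGlobal, NexisMicroglia, NexisTwoGene
from .model import propagate, build_laplacian, assemble_system_matrix
from .stats import (  # noqa: F401  (re-exported surface)
    fisher_compare, information_criteria, objective, per_timepoint_r,
    pooled_pearson_r, pooled_r2,
)

__all__ = [
    "fit_global", "fit_microglia", "fit_two_gene", "fit_gamma_only", "bootstrap",
    "pooled_r2", "pooled_pearson_r", "per_timepoint_r", "objective",
    "information_criteria", "fisher_compare",
]


def bootstrap(estimator, data: PathologyData, n_boot: int = 100, frac: float = 0.8,
              rng_seed=None) -> FitResult:
    """Region-resampling bootstrap of a (fitted or unfitted) estimator."""
    return estimator.fit_bootstrap(data, n_boot=n_boot, frac=frac,
                                   random_state=rng_seed)


def fit_global(conn: Connectome, data: PathologyData, bounds=None, n_starts: int = 10,
               rng_seed=None, variant: str = "global", n_boot: int = 100,
               frac: float = 0.8, symmetrize: bool = True,
               extra_starts=None) -> FitResult:
    """Stage one: fit the diffusion-only or global model, then bootstrap.

    ``variant`` selects "NDM" (γ, β) or "global" (γ, α, β). Pass ``n_boot=0``
    to skip the bootstrap (the result then carries no CIs).
    """
    cls = {"NDM": NDM, "global": NexisGlobal}[variant]
    est = cls(conn, symmetrize=symmetrize, bounds=bounds, n_starts=n_starts,
              extra_starts=extra_starts, random_state=rng_seed).fit(data)
    if n_boot:
        return est.fit_bootstrap(data, n_boot=n_boot, frac=frac, random_state=rng_seed)
    return est.result_


def fit_microglia(conn: Connectome, u, data: PathologyData, global_fit: FitResult | None,
                  rng_seed=None, anchor: bool = True, bounds=None, n_starts: int = 10,
                  n_boot: int = 100, frac: float = 0.8, symmetrize: bool = True,
                  extra_starts=None) -> FitResult:
    """Stage two: gene-modulated fit anchored to the global bootstrap CIs.

    With ``anchor=True``, ``global_fit`` must carry bootstrap CIs. With
    ``anchor=False`` all five parameters are fit by free multistart and
    ``global_fit`` may be None (used e.g. for nested-model comparisons).
    """
    est = NexisMicroglia(conn, u, global_result=global_fit, anchor=anchor,
                         symmetrize=symmetrize, bounds=bounds, n_starts=n_starts,
                         extra_starts=extra_starts, random_state=rng_seed).fit(data)
    if n_boot:
        return est.fit_bootstrap(data, n_boot=n_boot, frac=frac, random_state=rng_seed)
    return est.result_


def fit_two_gene(conn: Connectome, u1, u2, data: PathologyData,
                 global_fit: FitResult | None, rng_seed=None, anchor: bool = True,
                 bounds=None, n_starts: int = 10, n_boot: int = 100,
                 frac: float = 0.8, symmetrize: bool = True) -> FitResult:
    """Additive two-modulator fit (7 parameters); see :class:`NexisTwoGene`."""
    est = NexisTwoGene(conn, u1, gene2=u2, global_result=global_fit, anchor=anchor,
                       symmetrize=symmetrize, bounds=bounds, n_starts=n_starts,
                       random_state=rng_seed).fit(data)
    if n_boot:
        return est.fit_bootstrap(data, n_boot=n_boot, frac=frac, random_state=rng_seed)
    return est.result_


def fit_gamma_only(conn: Connectome, u, data_dilute: PathologyData,
                   fixed: NexisParams, rng_seed=None, gamma_bounds=(1e-8, 1e4),
                   symmetrize: bool = True) -> FitResult:
    """Refit only the seed rescale γ with all rate parameters held fixed.

    The model is linear in γ, so for fixed (α, β, p, b) the least-squares
    optimum is closed form: γ* = <x̂₁, y> / <x̂₁, x̂₁> with x̂₁ the unit-seed
    prediction, clipped into ``gamma_bounds``. Used for dilution-transfer
    experiments where the injectate concentration, but not the tau strain,
    changed.
    """
    L = build_laplacian(conn, symmetrize=symmetrize)
    uv = np.zeros(conn.n) if u is None else (
        u.values if hasattr(u, "values") else np.asarray(u, float).ravel()
    )
    accum = fixed.alpha + fixed.p * uv
    conduct = 1.0 + fixed.b * uv
    A = assemble_system_matrix(L, fixed.beta, accum, conduct)
    x0 = np.zeros(conn.n)
    x0[conn.index_of(data_dilute.seed_regions)] = 1.0
    pred1 = propagate(A, x0, data_dilute.times)[data_dilute.quantified_mask]
    obs = data_dilute.values[data_dilute.quantified_mask]
    denom = float(pred1 @ pred1)
    if denom == 0:
        raise ValueError("unit-seed prediction is identically zero; cannot fit gamma")
    gamma = float(np.clip(float(pred1 @ obs) / denom, *gamma_bounds))
    point = NexisParams(gamma=gamma, alpha=fixed.alpha, beta=fixed.beta,
                        p=fixed.p, b=fixed.b, variant=fixed.variant)
    resid = gamma * pred1 - obs
    sse = float(resid @ resid)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("diluted observations have zero variance")
    aic, bic = information_criteria(max(sse, np.finfo(float).tiny), obs.size, 1)
    return FitResult(point=point, r2=1.0 - sse / ss_tot, sse=sse, n_obs=obs.size,
                     k_params=1, aic=aic, bic=bic,
                     fixed=("alpha", "beta", "p", "b"), rng_seed=rng_seed)
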