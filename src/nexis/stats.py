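"""Fit statistics: pooled R², per-timepoint Pearson r, AIC/BIC, Fisher R-to-Z.

The headline fit statistic is a *pooled* coefficient of determination: one
SS_res/SS_tot ratio over all quantified region-timepoint pairs jointly, not a
per-timepoint correlation. A scale-sensitive loss is deliberate — pure network
diffusion can rank regions correctly while badly missing the overall scale of
pathology, and a pooled R² (which may be negative) exposes exactly that.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats as sps

from .datatypes import PathologyData, Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "pooled_r2", "pooled_pearson_r", "per_timepoint_r", "objective",
    "information_criteria", "fisher_compare",
]


def _paired(predicted, observed: PathologyData):
    P = predicted.values if isinstance(predicted, Trajectory) else np.asarray(predicted, float)
    if isinstance(predicted, Trajectory) and not np.allclose(predicted.times, observed.times):
        raise ValueError(
            f"prediction times {predicted.times} do not match "
            f"observation times {observed.times}"
        )
    if P.shape != observed.values.shape:
        raise ValueError(f"shape mismatch: predicted {P.shape}, observed {observed.values.shape}")
    m = observed.quantified_mask
    return P[m], observed.values[m]


def pooled_r2(predicted, observed: PathologyData) -> float:
    """R² = 1 - SS_res/SS_tot over the pooled quantified entries of all timepoints.

    May be negative when the model is worse than the observation mean.
    """
    pred, obs = _paired(predicted, observed)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observations have zero variance; R² undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def pooled_pearson_r(predicted, observed: PathologyData) -> float:
    """Pearson correlation of pooled predicted vs observed quantified entries.

    Well-defined even for poorly scaled fits, so it is the per-iteration
    statistic fed into the Fisher R-to-Z model comparison.
    """
    pred, obs = _paired(predicted, observed)
    if np.std(pred) == 0 or np.std(obs) == 0:
        log.warning("zero variance in pooled vectors; correlation undefined")
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1])


def per_timepoint_r(predicted, observed: PathologyData, t: float) -> float:
    """Pearson r between predicted and observed regions at a single timepoint."""
    P = predicted.values if isinstance(predicted, Trajectory) else np.asarray(predicted, float)
    hits = np.flatnonzero(np.isclose(observed.times, t))
    if hits.size != 1:
        raise ValueError(f"timepoint {t} not among observation times {observed.times}")
    k = hits[0]
    m = observed.quantified_mask[:, k]
    if m.sum() < 3:
        raise ValueError(f"need >= 3 quantified regions at t={t}, have {int(m.sum())}")
    x, y = P[m, k], observed.values[m, k]
    if np.std(x) == 0 or np.std(y) == 0:
        log.warning("zero variance at t=%s; Pearson r undefined", t)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def objective(params, conn, u, data: PathologyData, symmetrize: bool = True) -> float:
    """Sum of squared residuals over quantified entries for the simulated model.

    Minimizing this maximizes the pooled R²: SSE = SS_tot * (1 - R²).
    Simulation overflow maps to +inf (and is logged) so optimizers can recover.
    """
    from .model import SimulationOverflowError, simulate

    try:
        traj = simulate(conn, u, params, data.seed_regions, data.times,
                        symmetrize=symmetrize)
    except SimulationOverflowError as exc:
        log.warning("objective overflow at params %s: %s", params, exc)
        return float("inf")
    pred, obs = _paired(traj, data)
    return float(np.sum((obs - pred) ** 2))


def information_criteria(sse: float, n_obs: int, k_params: int) -> tuple[float, float]:
    """Gaussian least-squares AIC and BIC.

    AIC = n ln(SSE/n) + 2k and BIC = n ln(SSE/n) + k ln(n), with k counting
    every fitted parameter including the seed rescale γ. Additive constants
    are dropped, so only differences between models fit to the *same* data
    are meaningful.
    """
    if n_obs <= k_params:
        raise ValueError(f"need n_obs > k_params, got n={n_obs}, k={k_params}")
    if sse < 0:
        raise ValueError("sse must be nonnegative")
    if sse == 0:
        log.warning("zero SSE: information criteria are -inf (perfect fit)")
        return float("-inf"), float("-inf")
    base = n_obs * np.log(sse / n_obs)
    return float(base + 2 * k_params), float(base + k_params * np.log(n_obs))


def fisher_compare(boot_r_a, boot_r_b) -> tuple[float, float]:
    """Student's t test on Fisher R-to-Z transformed bootstrap correlations.

    Each per-iteration Pearson r is mapped through z = atanh(r); the two
    z-score samples are compared with a two-sample (equal-variance) t test.
    Returns (t statistic, two-sided p value). Correlations at |r| >= 1 are
    clipped to 1 - 1e-12 before the transform (and logged).
    """
    out = []
    for name, arr in (("A", boot_r_a), ("B", boot_r_b)):
        r = np.asarray(arr, dtype=float).ravel()
        r = r[np.isfinite(r)]
        if r.size < 2:
            raise ValueError(f"sample {name} needs >= 2 finite correlations")
        clipped = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        if np.any(clipped != r):
            log.info("clipped %d correlation(s) at |r| >= 1 in sample %s",
                     int(np.sum(clipped != r)), name)
        out.append(np.arctanh(clipped))
    t_stat, p_value = sps.ttest_ind(out[0], out[1], equal_var=True)
    return float(t_stat), float(p_value)
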