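"""Scikit-learn-style estimators for the network spread models.

Each estimator wraps one model variant:

* :class:`NDM` — pure network diffusion, parameters (γ, β).
* :class:`NexisGlobal` — diffusion plus a global accumulation/clearance rate,
  parameters (γ, α, β).
* :class:`NexisMicroglia` — gene-modulated accumulation and spread,
  parameters (γ, α, β, p, b).
* :class:`NexisTwoGene` — additive two-modulator extension, 7 parameters.

``fit`` minimizes the pooled sum of squared residuals between the simulated
trajectory and the quantified observations with bounded multistart
trust-region least squares; γ is always initialized at its closed-form
optimum given the rate parameters (the model is linear in the seed).
``fit_bootstrap`` refits on random 80% subsets of the quantified regions
(all timepoints of a region kept together) to obtain empirical 95% CIs.

The two-stage strategy mirrors the estimation pipeline for real data: fit
and bootstrap the global model first, then fit the gene model with (γ, α, β)
initialized at the global bootstrap means and box-bounded by the global 95%
CIs ("anchoring"), while (p, b) are fit free with multistart.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .datatypes import (
    Connectome, FitResult, GeneVector, NexisParams, PathologyData, Trajectory,
)
from .model import (
    SimulationOverflowError, assemble_system_matrix, build_laplacian, propagate,
)
from .stats import information_criteria, pooled_pearson_r, pooled_r2

log = logging.getLogger(__name__)

__all__ = ["NDM", "NexisGlobal", "NexisMicroglia", "NexisTwoGene", "FitFailureError"]

#: Default box bounds; γ > 0 and the global rates nonnegative, the
#: gene-modulated terms unbounded (they may legitimately be negative).
DEFAULT_BOUNDS = {
    "gamma": (1e-8, 1e4),
    "alpha": (0.0, 5.0),
    "beta": (0.0, 10.0),
    "p": (-np.inf, np.inf),
    "b": (-np.inf, np.inf),
    "p2": (-np.inf, np.inf),
    "b2": (-np.inf, np.inf),
}

_BIG_RESIDUAL = 1e8


class FitFailureError(RuntimeError):
    pass


def _draw_start(rng: np.random.Generator, name: str) -> float:
    """Log-uniform magnitudes for rates; random-signed magnitudes for p and b."""
    if name == "alpha":
        return 10.0 ** rng.uniform(-2, 0.5)
    if name == "beta":
        return 10.0 ** rng.uniform(-2, 1)
    if name in ("p", "p2"):
        return rng.choice([-1.0, 1.0]) * 10.0 ** rng.uniform(-2, 0)
    if name in ("b", "b2"):
        return rng.choice([-1.0, 1.0]) * 10.0 ** rng.uniform(-1, 0.7)
    raise ValueError(name)


class _NexisEstimatorBase(BaseEstimator):
    """Shared machinery; subclasses declare ``variant`` and ``param_names``."""

    variant: str = ""
    param_names: tuple[str, ...] = ()

    # ------------------------------------------------------------------ setup
    def _modulators(self) -> list[np.ndarray]:
        return []

    def _check_setup(self, data: PathologyData) -> None:
        if not isinstance(self.connectome, Connectome):
            raise TypeError("connectome must be a Connectome instance")
        if not isinstance(data, PathologyData):
            raise TypeError("data must be a PathologyData instance")
        if data.region_ids != self.connectome.region_ids:
            raise ValueError(
                "pathology regions are not aligned with the connectome; "
                "load both through the same region order"
            )

    def _accum_conduct(self, theta: dict) -> tuple[np.ndarray, np.ndarray]:
        n = self.connectome.n
        accum = np.full(n, theta.get("alpha", 0.0))
        conduct = np.ones(n)
        mods = self._modulators()
        pairs = [("p", "b"), ("p2", "b2")][: len(mods)]
        for u, (pn, bn) in zip(mods, pairs):
            accum = accum + theta.get(pn, 0.0) * u
            conduct = conduct + theta.get(bn, 0.0) * u
        return accum, conduct

    def _system_matrix(self, theta: dict) -> np.ndarray:
        accum, conduct = self._accum_conduct(theta)
        return assemble_system_matrix(self._L, theta["beta"], accum, conduct)

    def _predict_unit(self, theta: dict, times: np.ndarray) -> np.ndarray:
        """Trajectory for γ = 1 (the model is linear in γ)."""
        return propagate(self._system_matrix(theta), self._x0_unit, times)

    # ------------------------------------------------------------------- fit
    def _resolved_bounds(self) -> dict[str, tuple[float, float]]:
        bounds = {k: DEFAULT_BOUNDS[k] for k in self.param_names}
        for k, v in (self.bounds or {}).items():
            if k not in bounds:
                raise ValueError(f"bounds for unknown parameter {k!r}")
            lo, hi = float(v[0]), float(v[1])
            if not lo < hi:
                lo, hi = lo - max(1e-8, 1e-6 * abs(lo)), hi + max(1e-8, 1e-6 * abs(hi))
            bounds[k] = (lo, hi)
        return bounds

    def _closed_form_gamma(self, theta: dict, bounds) -> float:
        """argmin_γ SSE for fixed rates: γ* = <pred₁, obs> / <pred₁, pred₁>."""
        try:
            pred1 = self._predict_unit(theta, self._times)[self._mask]
        except SimulationOverflowError:
            return 1.0
        denom = float(pred1 @ pred1)
        g = float(pred1 @ self._obs) / denom if denom > 0 else 1.0
        lo, hi = bounds["gamma"]
        return float(np.clip(g if g > 0 else 1.0, lo, hi))

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        theta = dict(zip(self.param_names, x))
        try:
            pred = theta["gamma"] * self._predict_unit(theta, self._times)[self._mask]
        except SimulationOverflowError:
            return np.full(self._obs.size, _BIG_RESIDUAL)
        return pred - self._obs

    def _start_points(self, bounds, rng) -> list[np.ndarray]:
        rates = [n for n in self.param_names if n != "gamma"]
        raw: list[dict] = []
        for s in self.extra_starts or []:
            raw.append({n: float(s[n]) for n in rates if n in s})
        null = {n: 0.01 if n in ("alpha", "beta") else 0.0 for n in rates}
        null["beta"] = 1.0
        raw.append(null)  # modulator-free / near-diffusion start
        for _ in range(max(0, int(self.n_starts) - len(raw))):
            raw.append({n: _draw_start(rng, n) for n in rates})
        starts = []
        for cand in raw:
            theta = {n: float(np.clip(cand.get(n, 0.0), *bounds[n])) for n in rates}
            theta["gamma"] = self._closed_form_gamma(theta, bounds)
            starts.append(np.array([theta[n] for n in self.param_names]))
        return starts

    def fit(self, data: PathologyData, y=None):
        """Fit the model to observed pathology; returns self.

        Fitted attributes: ``params_`` (:class:`NexisParams`), ``theta_``
        (parameter dict), ``r2_``, ``sse_``, ``aic_``, ``bic_``, ``n_obs_``,
        ``result_`` (:class:`FitResult` without bootstrap), ``notes_``.
        """
        self._check_setup(data)
        self._prepare(data)
        bounds = self._resolved_bounds()
        rng = np.random.default_rng(self.random_state)
        lo = np.array([bounds[n][0] for n in self.param_names])
        hi = np.array([bounds[n][1] for n in self.param_names])

        best = None
        failures = []
        for x0 in self._start_points(bounds, rng):
            try:
                sol = least_squares(
                    self._residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
                    method="trf", xtol=self.tol, ftol=self.tol, gtol=self.tol,
                )
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(str(exc))
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitFailureError(
                f"all {self.n_starts} starts failed: {failures[:3]}"
            )
        self.theta_ = dict(zip(self.param_names, best.x))
        self.params_ = self._to_params(self.theta_)
        self.seed_regions_ = data.seed_regions
        self.times_ = data.times.copy()
        self.data_ = data
        self.notes_ = self._diagnostics(self.theta_)
        self._finalize_stats(data)
        return self

    def _diagnostics(self, theta: dict) -> tuple[str, ...]:
        notes = []
        _, conduct = self._accum_conduct(theta)
        if np.any(conduct <= 0):
            notes.append(
                f"{int((conduct <= 0).sum())} region(s) with effective "
                "conductance 1 + b*u <= 0 at the fitted parameters"
            )
            log.warning(notes[-1])
        return tuple(notes)

    def _finalize_stats(self, data: PathologyData) -> None:
        traj = self.predict(data.times)
        self.r2_ = pooled_r2(traj, data)
        pred, obs = traj.values[data.quantified_mask], data.values[data.quantified_mask]
        self.sse_ = float(np.sum((obs - pred) ** 2))
        self.n_obs_ = data.n_obs
        self.k_params_ = len(self.param_names)
        self.aic_, self.bic_ = information_criteria(
            max(self.sse_, np.finfo(float).tiny), self.n_obs_, self.k_params_
        )
        self.result_ = FitResult(
            point=self.params_, r2=self.r2_, sse=self.sse_, n_obs=self.n_obs_,
            k_params=self.k_params_, aic=self.aic_, bic=self.bic_,
            notes=self.notes_, rng_seed=self.random_state,
        )

    def _prepare(self, data: PathologyData) -> None:
        self._L = build_laplacian(self.connectome, symmetrize=self.symmetrize)
        x0 = np.zeros(self.connectome.n)
        x0[self.connectome.index_of(data.seed_regions)] = 1.0
        self._x0_unit = x0
        self._times = data.times
        self._mask = data.quantified_mask
        self._obs = data.values[self._mask]
        if self._obs.std() == 0:
            raise ValueError("observations have zero variance; nothing to fit")

    def _to_params(self, theta: dict) -> NexisParams:
        return NexisParams(variant=self.variant, **{
            k: float(theta.get(k, 0.0)) for k in
            ("gamma", "alpha", "beta", "p", "b", "p2", "b2")
        })

    # --------------------------------------------------------------- predict
    def predict(self, times=None) -> Trajectory:
        """Simulated trajectory at the fitted parameters (default: fit times)."""
        if not hasattr(self, "theta_"):
            raise RuntimeError("estimator is not fitted")
        t = self.times_ if times is None else np.asarray(times, dtype=float).ravel()
        values = self.theta_["gamma"] * self._predict_unit(self.theta_, t)
        return Trajectory(values, t, self.connectome.region_ids)

    def score(self, data: PathologyData, y=None) -> float:
        """Pooled R² of the fitted model against (possibly new) observations."""
        return pooled_r2(self.predict(data.times), data)

    # ------------------------------------------------------------- bootstrap
    def fit_bootstrap(
        self, data: PathologyData, n_boot: int = 100, frac: float = 0.8,
        random_state=None,
    ) -> FitResult:
        """Region-resampling bootstrap around the full-data fit.

        Each of ``n_boot`` iterations draws ``floor(frac * n_quantified)``
        quantified regions without replacement (keeping all timepoints of a
        sampled region together), refits from the full-data solution, and
        records the parameters, pooled R² and pooled Pearson r on the
        subsample. 95% CIs are the empirical 2.5/97.5 percentiles.
        """
        if n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if not 0 < frac <= 1:
            raise ValueError("frac must be in (0, 1]")
        if not hasattr(self, "theta_"):
            self.fit(data)
        bounds = self._resolved_bounds()
        lo = np.array([bounds[n][0] for n in self.param_names])
        hi = np.array([bounds[n][1] for n in self.param_names])
        x_full = np.clip(np.array([self.theta_[n] for n in self.param_names]), lo, hi)
        quantified = data.quantified_regions()
        m = int(math.floor(frac * quantified.size))
        if m < 2:
            raise ValueError("resample too small; increase frac or data size")
        rng = np.random.default_rng(random_state)
        full_mask, full_obs = self._mask, self._obs

        rows, skipped = [], 0
        for it in range(int(n_boot)):
            idx = rng.choice(quantified, size=m, replace=False)
            sub = data.subset_regions(idx)
            obs = sub.values[sub.quantified_mask]
            if obs.size < 3 or obs.std() == 0:
                skipped += 1
                log.warning("bootstrap iteration %d skipped: degenerate subsample", it)
                continue
            self._mask, self._obs = sub.quantified_mask, obs
            try:
                sol = least_squares(self._residuals, x_full, bounds=(lo, hi),
                                    method="trf", xtol=self.tol, ftol=self.tol,
                                    gtol=self.tol)
                theta = dict(zip(self.param_names, sol.x))
                traj = Trajectory(theta["gamma"] * self._predict_unit(theta, self._times),
                                  self._times, self.connectome.region_ids)
                row = {k: float(v) for k, v in theta.items()}
                row["r2"] = pooled_r2(traj, sub)
                row["r"] = pooled_pearson_r(traj, sub)
                rows.append(row)
            finally:
                self._mask, self._obs = full_mask, full_obs
        if len(rows) < 2:
            raise FitFailureError(f"bootstrap failed: only {len(rows)} usable iterations")
        boot = pd.DataFrame(rows)
        ci95 = {c: (float(np.percentile(boot[c], 2.5)), float(np.percentile(boot[c], 97.5)))
                for c in boot.columns}
        notes = self.notes_ + ((f"{skipped} bootstrap iteration(s) skipped",) if skipped else ())
        self.boot_ = boot
        self.ci95_ = ci95
        self.result_ = FitResult(
            point=self.params_, r2=self.r2_, sse=self.sse_, n_obs=self.n_obs_,
            k_params=self.k_params_, aic=self.aic_, bic=self.bic_,
            boot=boot, ci95=ci95, notes=notes, rng_seed=self.random_state,
        )
        return self.result_


class NDM(_NexisEstimatorBase):
    """Network diffusion model: dx/dt = -β L x, parameters (γ, β)."""

    variant = "NDM"
    param_names = ("gamma", "beta")

    def __init__(self, connectome=None, *, symmetrize=True, bounds=None,
                 n_starts=10, extra_starts=None, tol=1e-8, random_state=None):
        self.connectome = connectome
        self.symmetrize = symmetrize
        self.bounds = bounds
        self.n_starts = n_starts
        self.extra_starts = extra_starts
        self.tol = tol
        self.random_state = random_state


class NexisGlobal(_NexisEstimatorBase):
    """Global model: dx/dt = (αI - βL) x, parameters (γ, α, β)."""

    variant = "global"
    param_names = ("gamma", "alpha", "beta")

    def __init__(self, connectome=None, *, symmetrize=True, bounds=None,
                 n_starts=10, extra_starts=None, tol=1e-8, random_state=None):
        self.connectome = connectome
        self.symmetrize = symmetrize
        self.bounds = bounds
        self.n_starts = n_starts
        self.extra_starts = extra_starts
        self.tol = tol
        self.random_state = random_state


def _anchor_bounds(global_result: FitResult, bounds: dict | None) -> tuple[dict, dict]:
    """(bounds, extra start) anchoring (γ, α, β) to the global bootstrap CIs."""
    if global_result.ci95 is None or global_result.boot is None:
        raise ValueError(
            "anchoring needs a global FitResult with bootstrap CIs; "
            "run the global bootstrap first (or disable anchoring)"
        )
    means = global_result.boot_mean()
    out = dict(bounds or {})
    start = {}
    for k in ("gamma", "alpha", "beta"):
        lo, hi = global_result.ci95[k]
        out.setdefault(k, (lo, hi))
        start[k] = float(np.clip(means[k], lo, hi))
    return out, start


class NexisMicroglia(_NexisEstimatorBase):
    """Gene-modulated model, parameters (γ, α, β, p, b).

    With ``anchor=True`` (the second stage of the two-stage strategy) the
    shared parameters (γ, α, β) are initialized at the global bootstrap means
    and box-bounded by the global 95% CIs, preventing degenerate optima with
    biologically implausible global rates; (p, b) remain free. With
    ``anchor=False`` all five parameters are fit by free multistart.
    """

    variant = "microglia"
    param_names = ("gamma", "alpha", "beta", "p", "b")

    def __init__(self, connectome=None, gene=None, *, global_result=None,
                 anchor=True, symmetrize=True, bounds=None, n_starts=10,
                 extra_starts=None, tol=1e-8, random_state=None):
        self.connectome = connectome
        self.gene = gene
        self.global_result = global_result
        self.anchor = anchor
        self.symmetrize = symmetrize
        self.bounds = bounds
        self.n_starts = n_starts
        self.extra_starts = extra_starts
        self.tol = tol
        self.random_state = random_state

    def _gene_arrays(self) -> list[GeneVector]:
        return [self.gene]

    def _modulators(self) -> list[np.ndarray]:
        out = []
        for g in self._gene_arrays():
            if g is None:
                raise ValueError("a gene vector is required for this variant")
            v = g.values if isinstance(g, GeneVector) else np.asarray(g, float).ravel()
            if v.size != self.connectome.n:
                raise ValueError("gene vector length does not match the connectome")
            out.append(v)
        return out

    def _check_setup(self, data: PathologyData) -> None:
        super()._check_setup(data)
        for g in self._gene_arrays():
            if isinstance(g, GeneVector) and not g.normalized:
                raise ValueError(
                    f"gene vector {g.name!r} must be normalized to [0, 1] before fitting"
                )
        mods = self._modulators()
        if all(np.all(v == 0) for v in mods):
            log.warning("modulator is identically zero: p and b are unidentifiable")

    def fit(self, data: PathologyData, y=None):
        if self.anchor:
            anchored, start = _anchor_bounds(self.global_result, self.bounds)
            self._fit_bounds_override = anchored
            self._fit_extra = [dict(start)] + [
                dict(start, **s) for s in (self.extra_starts or [])
            ]
        else:
            self._fit_bounds_override = dict(self.bounds or {})
            self._fit_extra = list(self.extra_starts or [])
        prev_bounds, prev_extra = self.bounds, self.extra_starts
        try:
            self.bounds, self.extra_starts = self._fit_bounds_override, self._fit_extra
            super().fit(data)
        finally:
            self.bounds, self.extra_starts = prev_bounds, prev_extra
        mods = self._modulators()
        if all(np.all(v == 0) for v in mods):
            self.notes_ = self.notes_ + ("p and b unidentifiable: modulator is zero",)
            self.result_.notes = self.notes_
        return self

    def _resolved_bounds(self):
        prev = self.bounds
        self.bounds = getattr(self, "_fit_bounds_override", self.bounds)
        try:
            return super()._resolved_bounds()
        finally:
            self.bounds = prev


class NexisTwoGene(NexisMicroglia):
    """Additive two-modulator extension: accumulation α + p₁u₁ + p₂u₂ and
    conductance 1 + b₁u₁ + b₂u₂ (7 parameters). Reduces exactly to the
    single-gene model when the second modulator is zero."""

    variant = "two_gene"
    param_names = ("gamma", "alpha", "beta", "p", "b", "p2", "b2")

    def __init__(self, connectome=None, gene=None, gene2=None, *, global_result=None,
                 anchor=True, symmetrize=True, bounds=None, n_starts=10,
                 extra_starts=None, tol=1e-8, random_state=None):
        super().__init__(connectome, gene, global_result=global_result,
                         anchor=anchor, symmetrize=symmetrize, bounds=bounds,
                         n_starts=n_starts, extra_starts=extra_starts, tol=tol,
                         random_state=random_state)
        self.gene2 = gene2

    def _gene_arrays(self):
        return [self.gene, self.gene2]

    def _check_setup(self, data: PathologyData) -> None:
        super()._check_setup(data)
        u1, u2 = self._modulators()
        if np.std(u1) > 0 and np.std(u2) > 0:
            r = float(np.corrcoef(u1, u2)[0, 1])
            if abs(r) > 0.99:
                log.warning("modulators nearly collinear (|r| = %.3f): "
                            "(p, b) vs (p2, b2) are unidentifiable", abs(r))
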