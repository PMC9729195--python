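"""Core containers: connectome, gene vectors, pathology observations, parameters.

All containers are lightweight dataclasses validated on construction. Region
order is the single source of alignment: every array is ordered like
``Connectome.region_ids`` and loaders resolve files to that order by label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

HEMISPHERE_TAGS = ("left", "right", "none")

VARIANTS = ("NDM", "global", "microglia", "two_gene")


class InvalidConnectomeError(ValueError):
    pass


class DegenerateGeneError(ValueError):
    pass


class UnknownRegionError(KeyError):
    def __init__(self, missing, valid):
        self.missing = tuple(missing)
        self.valid = tuple(valid)
        super().__init__(
            f"unknown region label(s) {sorted(self.missing)}; "
            f"valid labels are {sorted(self.valid)}"
        )


def _as_labels(labels: Sequence[str]) -> tuple[str, ...]:
    out = tuple(str(x) for x in labels)
    if len(set(out)) != len(out):
        dupes = sorted({x for x in out if out.count(x) > 1})
        raise ValueError(f"duplicate region labels: {dupes}")
    return out


@dataclass(frozen=True)
class Connectome:
    """Weighted inter-regional connectivity graph.

    Parameters
    ----------
    weights : (n, n) array
        Nonnegative connection strengths ``c_ij`` (arbitrary units). The
        diagonal is zeroed on construction: self-connections carry no meaning
        for inter-regional flow.
    region_ids : sequence of str
        Unique region labels aligned with the matrix order.
    hemisphere : sequence of {"left", "right", "none"}, optional
        Per-region hemisphere tag; defaults to "none" everywhere.
    """

    weights: np.ndarray
    region_ids: tuple[str, ...]
    hemisphere: tuple[str, ...] = ()

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise InvalidConnectomeError(f"weights must be square, got shape {W.shape}")
        if W.shape[0] < 2:
            raise InvalidConnectomeError("a connectome needs at least 2 regions")
        if not np.all(np.isfinite(W)):
            raise InvalidConnectomeError("weights contain non-finite entries")
        if np.any(W < 0):
            i, j = np.argwhere(W < 0)[0]
            raise InvalidConnectomeError(f"negative weight at ({i}, {j}): {W[i, j]}")
        W = W.copy()
        np.fill_diagonal(W, 0.0)
        labels = _as_labels(self.region_ids)
        if len(labels) != W.shape[0]:
            raise InvalidConnectomeError(
                f"{len(labels)} labels for a {W.shape[0]}-region matrix"
            )
        hemi = tuple(self.hemisphere) or ("none",) * len(labels)
        if len(hemi) != len(labels):
            raise InvalidConnectomeError("hemisphere tags misaligned with regions")
        bad = sorted(set(hemi) - set(HEMISPHERE_TAGS))
        if bad:
            raise InvalidConnectomeError(f"unknown hemisphere tag(s): {bad}")
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "region_ids", labels)
        object.__setattr__(self, "hemisphere", hemi)

    @property
    def n(self) -> int:
        return len(self.region_ids)

    def index_of(self, labels: Sequence[str]) -> np.ndarray:
        """Map region labels to matrix indices, erroring on unknown labels."""
        lookup = {r: i for i, r in enumerate(self.region_ids)}
        missing = [x for x in labels if x not in lookup]
        if missing:
            raise UnknownRegionError(missing, self.region_ids)
        return np.array([lookup[x] for x in labels], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.region_ids, columns=self.region_ids)


@dataclass(frozen=True)
class GeneVector:
    """Per-region modulator expression ``u`` entering the conductance (1 + b·u).

    ``normalized`` records whether values were min-max rescaled to [0, 1];
    fitting requires it, but dose-scaled vectors deliberately leave the range.
    """

    values: np.ndarray
    name: str = "gene"
    normalized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError(f"gene vector {self.name!r} has non-finite values")
        if self.normalized and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError(f"gene vector {self.name!r} flagged normalized but outside [0, 1]")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ExpressionTable:
    """Region x gene expression matrix aligned with a connectome's region order."""

    values: np.ndarray
    gene_names: tuple[str, ...]
    region_ids: tuple[str, ...]

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2:
            raise ValueError("expression values must be 2-D (regions x genes)")
        if not np.all(np.isfinite(V)):
            raise ValueError("expression table has non-finite entries (impute on load)")
        genes = tuple(str(g) for g in self.gene_names)
        regions = _as_labels(self.region_ids)
        if V.shape != (len(regions), len(genes)):
            raise ValueError(
                f"shape {V.shape} inconsistent with {len(regions)} regions x {len(genes)} genes"
            )
        object.__setattr__(self, "values", V)
        object.__setattr__(self, "gene_names", genes)
        object.__setattr__(self, "region_ids", regions)

    def column(self, gene: str) -> np.ndarray:
        try:
            j = self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in table (have {list(self.gene_names)})")
        return self.values[:, j]


@dataclass(frozen=True)
class NexisParams:
    """Model parameters (γ, α, β, p, b) plus the variant tag.

    gamma : seed rescale, pathology units injected at t=0 (> 0)
    alpha : global accumulation (>0) / clearance (<0) rate, per week
    beta  : global diffusivity rate, per week (>= 0)
    p     : modulator-dependent accumulation rate, per week per unit u
    b     : modulator-dependent spread modulation, dimensionless per unit u
    p2, b2: second-gene terms (two-gene variant only)
    """

    gamma: float
    alpha: float = 0.0
    beta: float = 0.0
    p: float = 0.0
    b: float = 0.0
    p2: float = 0.0
    b2: float = 0.0
    variant: str = "microglia"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.variant == "NDM" and (self.alpha or self.p or self.b):
            raise ValueError("NDM requires alpha = p = b = 0")
        if self.variant == "global" and (self.p or self.b):
            raise ValueError("Nexis:global requires p = b = 0")
        if self.variant != "two_gene" and (self.p2 or self.b2):
            raise ValueError("p2/b2 are only meaningful for the two-gene variant")

    def as_dict(self) -> dict:
        d = {"gamma": self.gamma, "alpha": self.alpha, "beta": self.beta,
             "p": self.p, "b": self.b, "variant": self.variant}
        if self.variant == "two_gene":
            d["p2"], d["b2"] = self.p2, self.b2
        return d


@dataclass(frozen=True)
class Trajectory:
    """Simulated pathology x_i(t): regions x timepoints, times in weeks."""

    values: np.ndarray
    times: np.ndarray
    region_ids: tuple[str, ...] = ()

    def __post_init__(self):
        V = np.atleast_2d(np.asarray(self.values, dtype=float))
        t = np.asarray(self.times, dtype=float).ravel()
        if V.shape[1] != t.size:
            raise ValueError(f"{V.shape[1]} columns for {t.size} timepoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(V)):
            raise ValueError("trajectory contains non-finite values")
        regions = _as_labels(self.region_ids) if self.region_ids else tuple(
            f"r{i}" for i in range(V.shape[0])
        )
        if len(regions) != V.shape[0]:
            raise ValueError("region labels misaligned with trajectory rows")
        object.__setattr__(self, "values", V)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "region_ids", regions)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (region, time_weeks, value) table."""
        n, T = self.values.shape
        return pd.DataFrame({
            "region": np.repeat(self.region_ids, T),
            "time_weeks": np.tile(self.times, n),
            "value": self.values.ravel(),
        })


@dataclass(frozen=True)
class PathologyData:
    """Observed regional pathology at a few sacrifice timepoints.

    Missing (unquantified) entries are NaN in ``values`` and False in
    ``quantified_mask``. ``seed_regions`` names where pathology was injected.
    """

    values: np.ndarray
    times: np.ndarray
    region_ids: tuple[str, ...]
    seed_regions: tuple[str, ...]
    quantified_mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        V = np.atleast_2d(np.asarray(self.values, dtype=float))
        t = np.asarray(self.times, dtype=float).ravel()
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and positive")
        if V.shape[1] != t.size:
            raise ValueError(f"{V.shape[1]} columns for {t.size} timepoints")
        regions = _as_labels(self.region_ids)
        if len(regions) != V.shape[0]:
            raise ValueError("region labels misaligned with pathology rows")
        mask = self.quantified_mask
        mask = np.isfinite(V) if mask is None else (np.asarray(mask, bool) & np.isfinite(V))
        if mask.shape != V.shape:
            raise ValueError("quantified_mask shape mismatch")
        if not mask.any(axis=0).all():
            empty = t[~mask.any(axis=0)]
            raise ValueError(f"no quantified entries at timepoint(s) {empty} weeks")
        seeds = tuple(str(s) for s in self.seed_regions)
        if not seeds:
            raise ValueError("seed_regions must be nonempty")
        unknown = sorted(set(seeds) - set(regions))
        if unknown:
            raise UnknownRegionError(unknown, regions)
        object.__setattr__(self, "values", V)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "region_ids", regions)
        object.__setattr__(self, "seed_regions", seeds)
        object.__setattr__(self, "quantified_mask", mask)

    @property
    def n_obs(self) -> int:
        return int(self.quantified_mask.sum())

    def quantified_regions(self) -> np.ndarray:
        """Indices of regions with at least one quantified observation."""
        return np.flatnonzero(self.quantified_mask.any(axis=1))

    def subset_regions(self, region_idx: np.ndarray) -> "PathologyData":
        """Restrict the quantified mask to the given regions (all timepoints kept)."""
        keep = np.zeros(len(self.region_ids), dtype=bool)
        keep[np.asarray(region_idx, int)] = True
        mask = self.quantified_mask & keep[:, None]
        return PathologyData(self.values, self.times, self.region_ids,
                             self.seed_regions, quantified_mask=mask)


@dataclass
class FitResult:
    """Point fit plus optional bootstrap distributions and 95% CIs.

    ``point`` is the full-data fit; ``boot`` holds per-iteration parameter,
    R² and pooled Pearson-r draws; ``ci95`` maps parameter name to the
    empirical 2.5/97.5 percentile interval of the bootstrap draws.
    """

    point: NexisParams
    r2: float
    sse: float
    n_obs: int
    k_params: int
    aic: float
    bic: float
    boot: pd.DataFrame | None = None
    ci95: dict[str, tuple[float, float]] | None = None
    fixed: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()
    rng_seed: int | None = None

    def boot_mean(self) -> dict[str, float]:
        if self.boot is None:
            raise ValueError("no bootstrap draws recorded; run the bootstrap first")
        return {c: float(self.boot[c].mean()) for c in self.boot.columns}

    @property
    def boot_r(self) -> np.ndarray:
        if self.boot is None or "r" not in self.boot:
            raise ValueError("no bootstrap correlation draws recorded")
        return self.boot["r"].to_numpy()

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.point.as_dict(),
            "r2": self.r2, "sse": self.sse, "n_obs": self.n_obs,
            "k_params": self.k_params, "aic": self.aic, "bic": self.bic,
            "ci95": {k: list(v) for k, v in (self.ci95 or {}).items()},
            "fixed": list(self.fixed), "notes": list(self.notes),
            "rng_seed": self.rng_seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text
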