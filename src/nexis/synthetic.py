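"""Synthetic connectomes, gene vectors and noisy pathology observations.

The generator emulates the structure the inference pipeline assumes for real
mouse data: a bihemispheric connectome whose left and right intra-hemisphere
blocks are mirror images (the real atlas parcellation has 213 regions per
hemisphere; the desk-scale default is 20), positive right-skewed regional
gene expression, and pathology trajectories produced by the spread model
itself from a single-region seed, observed at a few sacrifice timepoints with
multiplicative lognormal noise and a fraction of regions left unquantified.

Default true parameters are a realistic gene-modulated regime for a
hippocampal-seeding tauopathy experiment: γ=2.48, α=0.25/wk, β=1.30/wk,
p=−0.29 (modulator-enhanced clearance), b=1.33 (modulator-enhanced spread),
observed at 4, 8 and 12 weeks. All generators are pure functions of
``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.sparse.csgraph import connected_components

from .datatypes import Connectome, ExpressionTable, GeneVector, NexisParams, PathologyData, Trajectory
from .genes import HOMEOSTASIS_GENES, normalize_gene
from .model import simulate

__all__ = ["SyntheticSpec", "SyntheticDataset", "gen_connectome", "gen_gene",
           "gen_expression_table", "gen_pathology", "make_dataset"]

_DEFAULT_TRUTH = NexisParams(gamma=2.48, alpha=0.25, beta=1.30,
                             p=-0.29, b=1.33, variant="microglia")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration.

    n_regions_per_hemi : regions per hemisphere (total is twice this)
    density            : edge probability within and between hemispheres
    weight_scale       : sigma of the lognormal edge-weight distribution
    true_params        : parameters the pathology is simulated from
    gene_model         : "lognormal" (i.i.d. positive) or
                         "latent-factor-8-gene" (8 genes sharing one factor)
    noise_sd           : sd of multiplicative lognormal observation noise
    times              : observation times, weeks
    quantified_frac    : fraction of regions with quantified observations
    rng_seed           : seed; generation is a pure function of it
    """

    n_regions_per_hemi: int = 20
    density: float = 0.25
    weight_scale: float = 1.0
    true_params: NexisParams = _DEFAULT_TRUTH
    gene_model: str = "lognormal"
    noise_sd: float = 0.10
    times: tuple[float, ...] = (4.0, 8.0, 12.0)
    quantified_frac: float = 0.9
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.quantified_frac <= 1:
            raise ValueError("quantified_frac must be in (0, 1]")
        if self.n_regions_per_hemi < 2:
            raise ValueError("need at least 2 regions per hemisphere")
        if self.gene_model not in ("lognormal", "latent-factor-8-gene"):
            raise ValueError(f"unknown gene_model {self.gene_model!r}")


class SyntheticDataset(NamedTuple):
    """A generated study: inputs, observations and the generating truth."""

    connectome: Connectome
    gene: GeneVector
    data: PathologyData
    truth: Trajectory
    params: NexisParams
    expression: ExpressionTable | None = None


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng(np.random.SeedSequence((int(spec.rng_seed), stream)))


def _symmetric_lognormal(rng, n, density, sigma, with_diagonal=False) -> np.ndarray:
    # with_diagonal covers inter-hemisphere blocks, whose diagonal holds the
    # homotopic (mirror-region) connections
    iu = np.triu_indices(n, k=0 if with_diagonal else 1)
    w = np.zeros((n, n))
    present = rng.random(iu[0].size) < density
    vals = rng.lognormal(mean=0.0, sigma=sigma, size=iu[0].size) * present
    w[iu] = vals
    w = w + w.T
    if with_diagonal:
        w[np.diag_indices(n)] /= 2.0
    return w


def gen_connectome(spec: SyntheticSpec) -> Connectome:
    """Bihemispheric mirror-symmetric weighted connectome.

    Left and right intra-hemisphere blocks are identical (mirror symmetry of
    the parcellation); the inter-hemisphere block is symmetric so the full
    matrix satisfies C = Cᵀ. Disconnected draws are rejected (up to 10
    regenerations) because diffusion cannot reach an isolated component.
    """
    n = spec.n_regions_per_hemi
    for attempt in range(10):
        rng = _rng(spec, 100 + attempt)
        intra = _symmetric_lognormal(rng, n, spec.density, spec.weight_scale)
        inter = _symmetric_lognormal(rng, n, spec.density, spec.weight_scale,
                                     with_diagonal=True)
        C = np.block([[intra, inter], [inter.T, intra]])
        # scale to mean node degree 1 so diffusion rates are O(1) per week,
        # matching the normalization convention of atlas connectomes
        degree = C.sum(axis=1).mean()
        if degree > 0:
            C = C / degree
        n_comp, _ = connected_components(C > 0, directed=False)
        if n_comp == 1:
            labels = tuple(f"L{i+1:02d}" for i in range(n)) + tuple(
                f"R{i+1:02d}" for i in range(n))
            hemi = ("left",) * n + ("right",) * n
            return Connectome(C, labels, hemi)
    raise RuntimeError(
        f"could not generate a connected graph at density {spec.density} "
        "after 10 attempts; increase density"
    )


def gen_gene(spec: SyntheticSpec, conn: Connectome) -> GeneVector:
    """Positive regional modulator expression, min-max normalized to [0, 1]."""
    if spec.gene_model == "latent-factor-8-gene":
        _, gene = gen_expression_table(spec, conn)
        return gene
    rng = _rng(spec, 200)
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=conn.n)
    return normalize_gene(raw, name="synthetic-gene")


def gen_expression_table(
    spec: SyntheticSpec, conn: Connectome, noise_sd: float = 0.1
) -> tuple[ExpressionTable, GeneVector]:
    """Eight homeostasis-named genes sharing one positive latent factor.

    Gene g is loading_g * factor + noise, enabling recovery tests of the PC1
    signature. Returns the table and the (normalized) latent factor.
    """
    rng = _rng(spec, 300)
    factor = rng.lognormal(mean=0.0, sigma=1.0, size=conn.n)
    loadings = rng.uniform(0.5, 1.5, size=len(HOMEOSTASIS_GENES))
    X = factor[:, None] * loadings[None, :]
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd * X.std(), size=X.shape)
    table = ExpressionTable(X, HOMEOSTASIS_GENES, conn.region_ids)
    return table, normalize_gene(factor, name="synthetic-latent-factor")


def gen_pathology(
    spec: SyntheticSpec, conn: Connectome, u, seed_region: str | None = None
) -> tuple[PathologyData, Trajectory]:
    """Noisy observations of a model-generated trajectory.

    The trajectory is simulated from ``spec.true_params`` seeded at a single
    region (default: the first left-hemisphere region, standing in for the
    hippocampal injection site). Each observation is multiplied by
    exp(N(0, noise_sd²)); a random (1 - quantified_frac) fraction of
    non-seed regions is masked as unquantified at all timepoints, mirroring
    regions that could not be scored.
    """
    rng = _rng(spec, 400)
    seed = seed_region or conn.region_ids[0]
    truth = simulate(conn, u, spec.true_params, [seed], spec.times)
    obs = truth.values * rng.lognormal(mean=0.0, sigma=spec.noise_sd,
                                       size=truth.values.shape) \
        if spec.noise_sd > 0 else truth.values.copy()
    n_keep = max(2, int(round(spec.quantified_frac * conn.n)))
    seed_idx = conn.index_of([seed])[0]
    others = np.setdiff1d(np.arange(conn.n), [seed_idx])
    kept = {seed_idx, *rng.choice(others, size=n_keep - 1, replace=False)}
    mask = np.zeros_like(obs, dtype=bool)
    mask[sorted(kept), :] = True
    values = np.where(mask, obs, np.nan)
    data = PathologyData(values, truth.times, conn.region_ids, (seed,),
                         quantified_mask=mask)
    return data, truth


def make_dataset(spec: SyntheticSpec | None = None, **overrides) -> SyntheticDataset:
    """One-call generation of a full synthetic study."""
    spec = replace(spec or SyntheticSpec(), **overrides) if overrides else (spec or SyntheticSpec())
    conn = gen_connectome(spec)
    expression = None
    if spec.gene_model == "latent-factor-8-gene":
        expression, gene = gen_expression_table(spec, conn)
    else:
        gene = gen_gene(spec, conn)
    data, truth = gen_pathology(spec, conn, gene)
    return SyntheticDataset(conn, gene, data, truth, spec.true_params, expression)
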