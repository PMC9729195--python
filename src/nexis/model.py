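"""The gene-modulated network-diffusion dynamical system and its forward solution.

The models are linear time-invariant systems on the connectome graph,

    dx/dt = [Lam(u) - beta * Lt(u)] x,       x(0) = gamma * (seed indicator)

with Lam(u) = diag(alpha + p*u_i) the local accumulation/clearance term and
Lt(u) = (D - C) @ diag(1 + b*u_i) the modulated graph Laplacian, so that row i
of -beta*Lt(u)x equals beta * sum_j c_ij [(1 + u_j b) x_j - (1 + u_i b) x_i].
Variants: NDM (alpha = p = b = 0, pure diffusion), Nexis:global (p = b = 0),
Nexis:microglia (all five parameters). Solutions use the matrix exponential,
which is exact for a linear system; adaptive ODE integration is kept only as
an independent test oracle.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .datatypes import Connectome, GeneVector, NexisParams, Trajectory

__all__ = [
    "build_laplacian", "build_modulated_laplacian", "system_matrix",
    "make_seed", "simulate", "edge_flow", "NegativeConductanceWarning",
    "SimulationOverflowError",
]


class NegativeConductanceWarning(UserWarning):
    """1 + b*u_i <= 0 somewhere: an edge has non-physical negative conductance."""


class SimulationOverflowError(OverflowError):
    """The matrix exponential overflowed (e.g. extreme alpha * t)."""


def _gene_values(u, n: int) -> np.ndarray:
    if u is None:
        return np.zeros(n)
    v = u.values if isinstance(u, GeneVector) else np.asarray(u, dtype=float).ravel()
    if v.size != n:
        raise ValueError(f"gene vector length {v.size} != {n} regions")
    return v


def _connectivity(conn: Connectome, symmetrize: bool) -> np.ndarray:
    C = conn.weights
    return (C + C.T) / 2.0 if symmetrize else C


def build_laplacian(conn: Connectome, symmetrize: bool = True) -> np.ndarray:
    """Graph Laplacian L = D - C with D = diag(row sums).

    With ``symmetrize`` (default) C is replaced by (C + C^T)/2 first, matching
    the pairwise-symmetric form of the two-region diffusion equation. Every
    row of L sums to zero, so a spatially uniform state is a diffusion fixed
    point.
    """
    C = _connectivity(conn, symmetrize)
    return np.diag(C.sum(axis=1)) - C


def build_modulated_laplacian(
    conn: Connectome, u, b: float, symmetrize: bool = True
) -> np.ndarray:
    """Modulated Laplacian Lt(u) = (D - C) @ diag(1 + b*u).

    This is the unique linear operator whose row i applied to x gives
    -sum_j c_ij[(1 + u_j b) x_j - (1 + u_i b) x_i]; it reduces to L exactly
    when b = 0 or u = 0. Negative effective conductances (1 + b*u_i <= 0) are
    permitted — fits may explore negative b — but raise a warning.
    """
    v = _gene_values(u, conn.n)
    conductance = 1.0 + b * v
    if np.any(conductance <= 0):
        warnings.warn(
            f"{int((conductance <= 0).sum())} region(s) have effective "
            f"conductance 1 + b*u <= 0 (b={b})",
            NegativeConductanceWarning,
            stacklevel=2,
        )
    return build_laplacian(conn, symmetrize=symmetrize) * conductance[None, :]


def system_matrix(
    conn: Connectome, u, params: NexisParams, symmetrize: bool = True
) -> np.ndarray:
    """System matrix A = Lam(u) - beta * Lt(u) of dx/dt = A x.

    Variant NDM gives A = -beta*L; Nexis:global gives A = -beta*L + alpha*I.
    """
    v = _gene_values(u, conn.n)
    L = build_laplacian(conn, symmetrize=symmetrize)
    return assemble_system_matrix(
        L, params.beta,
        accumulation=params.alpha + params.p * v,
        conductance=1.0 + params.b * v,
    )


def assemble_system_matrix(
    L: np.ndarray, beta: float, accumulation: np.ndarray, conductance: np.ndarray
) -> np.ndarray:
    """A = diag(accumulation) - beta * L @ diag(conductance); fast inner kernel."""
    A = -beta * (L * np.asarray(conductance)[None, :])
    A[np.diag_indices_from(A)] += np.asarray(accumulation)
    return A


def make_seed(conn: Connectome, seed_regions: Sequence[str], gamma: float) -> np.ndarray:
    """Initial condition x(0): value gamma at each seed region, zero elsewhere.

    The injected amount is unknown in seeding experiments, so the binary seed
    indicator is rescaled by the fitted gamma.
    """
    if not gamma > 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    seeds = list(seed_regions)
    if not seeds:
        raise ValueError("seed_regions must be nonempty")
    x0 = np.zeros(conn.n)
    x0[conn.index_of(seeds)] = gamma
    return x0


def propagate(A: np.ndarray, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """exp(A t) x0 at each time; raises on overflow instead of returning inf."""
    times = np.asarray(times, dtype=float)
    out = np.empty((x0.size, times.size))
    for k, t in enumerate(times):
        with np.errstate(over="ignore", invalid="ignore"):
            xt = expm(A * t) @ x0
        if not np.all(np.isfinite(xt)):
            raise SimulationOverflowError(
                f"matrix exponential overflowed at t = {t} weeks "
                "(accumulation rate * time too large)"
            )
        out[:, k] = xt
    return out


def simulate(
    conn: Connectome,
    u,
    params: NexisParams,
    seed_regions: Sequence[str],
    times: Sequence[float],
    symmetrize: bool = True,
) -> Trajectory:
    """Solve the model forward: x(t) = expm(A t) x(0) at each requested time."""
    t = np.asarray(times, dtype=float).ravel()
    if t.size == 0:
        raise ValueError("at least one output time is required")
    if np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ValueError("times must be strictly increasing with times[0] >= 0")
    A = system_matrix(conn, u, params, symmetrize=symmetrize)
    x0 = make_seed(conn, seed_regions, params.gamma)
    return Trajectory(propagate(A, x0, t), t, conn.region_ids)


def edge_flow(
    conn: Connectome, u, params: NexisParams, x: np.ndarray,
    u2=None, symmetrize: bool = True,
) -> np.ndarray:
    """Instantaneous net flow matrix f_ij = beta*c_ij[(1+u_j b)x_j - (1+u_i b)x_i].

    f_ij is the flow into region i from region j implied by the state x;
    for symmetric C the matrix is antisymmetric. For the two-gene variant pass
    ``u2``: the conductance becomes 1 + b*u1 + b2*u2.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != conn.n:
        raise ValueError(f"state length {x.size} != {conn.n} regions")
    if not np.all(np.isfinite(x)):
        raise ValueError("state x must be finite")
    conductance = 1.0 + params.b * _gene_values(u, conn.n)
    if params.variant == "two_gene":
        if u2 is None:
            raise ValueError("two-gene flow needs the second modulator vector u2")
        conductance = conductance + params.b2 * _gene_values(u2, conn.n)
    C = _connectivity(conn, symmetrize)
    g = conductance * x
    return params.beta * C * (g[None, :] - g[:, None])
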