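"""In-silico experiments: model comparison, gene dose-response, flow maps.

These orchestrate the estimators into the standard analyses: a model
comparison table (NDM vs global vs one gene model per modulator, with
bootstrap CIs and Fisher R-to-Z significance), the knock-down/over-expression
dose-response sweep (expression scaled by powers of two), per-edge flow
differencing between two fitted models, and the additive two-gene fit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import Connectome, FitResult, NexisParams, PathologyData
from .genes import DOSE_EXPONENTS, scale_gene
from .inference import fisher_compare, fit_global, fit_microglia, fit_two_gene
from .model import edge_flow, simulate

log = logging.getLogger(__name__)

__all__ = ["compare_models", "dose_response", "flow_difference", "two_gene_fit"]

_PARAM_COLS = ("gamma", "alpha", "beta", "p", "b")


def _row(model: str, res: FitResult) -> dict:
    row: dict = {"model": model, "r2": res.r2, "aic": res.aic, "bic": res.bic,
                 "n_obs": res.n_obs, "k_params": res.k_params}
    for k in _PARAM_COLS:
        row[k] = getattr(res.point, k)
        if res.ci95 and k in res.ci95:
            row[f"{k}_lo"], row[f"{k}_hi"] = res.ci95[k]
    if res.notes:
        row["notes"] = "; ".join(res.notes)
    return row


def compare_models(
    conn: Connectome,
    data: PathologyData,
    gene_vectors: dict,
    rng_seed=None,
    n_boot: int = 100,
    frac: float = 0.8,
    n_starts: int = 10,
    anchor: bool = True,
    symmetrize: bool = True,
) -> pd.DataFrame:
    """One comparison row per model: NDM, global, then one per gene vector.

    Each model is fit and bootstrapped; gene models are anchored to the
    global bootstrap CIs (disable with ``anchor=False``). Fisher R-to-Z
    p-values compare each richer model's bootstrap correlation draws against
    NDM's, and each gene model's against the global model's. Per-model fit
    failures are reported in an ``error`` column rather than raised.
    """
    if not gene_vectors:
        raise ValueError("at least one gene vector is required")
    rows: list[dict] = []
    seed = None if rng_seed is None else int(rng_seed)

    ndm = fit_global(conn, data, variant="NDM", rng_seed=seed, n_boot=n_boot,
                     frac=frac, n_starts=n_starts, symmetrize=symmetrize)
    rows.append(_row("NDM", ndm))

    glob = fit_global(conn, data, variant="global", rng_seed=seed, n_boot=n_boot,
                      frac=frac, n_starts=n_starts, symmetrize=symmetrize,
                      extra_starts=[{"alpha": 0.0, "beta": ndm.point.beta}])
    g_row = _row("global", glob)
    _, g_row["fisher_p_vs_ndm"] = fisher_compare(glob.boot_r, ndm.boot_r)
    rows.append(g_row)

    for name, u in gene_vectors.items():
        try:
            res = fit_microglia(
                conn, u, data, glob, rng_seed=seed, anchor=anchor, n_boot=n_boot,
                frac=frac, n_starts=n_starts, symmetrize=symmetrize,
                extra_starts=None if anchor else [
                    {"alpha": glob.point.alpha, "beta": glob.point.beta,
                     "p": 0.0, "b": 0.0}],
            )
        except Exception as exc:
            log.warning("fit failed for gene model %r: %s", name, exc)
            rows.append({"model": name, "error": str(exc)})
            continue
        row = _row(name, res)
        _, row["fisher_p_vs_ndm"] = fisher_compare(res.boot_r, ndm.boot_r)
        _, row["fisher_p_vs_global"] = fisher_compare(res.boot_r, glob.boot_r)
        rows.append(row)
    return pd.DataFrame(rows)


def dose_response(
    conn: Connectome,
    u,
    fitted: NexisParams,
    seed_regions,
    report_regions,
    end_time: float = 12.0,
    exponents=DOSE_EXPONENTS,
    symmetrize: bool = True,
) -> pd.DataFrame:
    """End-time pathology under expression scaled by 2^k for each exponent k.

    ``report_regions`` is either a list of region labels or a mapping
    {group name: [member labels]}; groups report the mean over members
    (anatomical grouping is a data concern, supplied by the caller). Columns
    are labelled ``2^k``; the k = 0 column is the unscaled baseline.
    """
    if isinstance(report_regions, dict):
        groups = {k: list(v) for k, v in report_regions.items()}
    else:
        groups = {r: [r] for r in report_regions}
    idx = {name: conn.index_of(members) for name, members in groups.items()}

    out: dict[str, list[float]] = {name: [] for name in groups}
    for k in exponents:
        scaled = scale_gene(u, k, allow_extreme=True)
        traj = simulate(conn, scaled, fitted, seed_regions, [end_time],
                        symmetrize=symmetrize)
        x_end = traj.values[:, -1]
        for name in groups:
            out[name].append(float(x_end[idx[name]].mean()))
    table = pd.DataFrame(out, index=[f"2^{k}" for k in exponents]).T
    table.index.name = "region"
    return table


def flow_difference(
    conn: Connectome,
    u,
    params_a: NexisParams,
    params_b: NexisParams,
    x_a: np.ndarray,
    x_b: np.ndarray,
    u2=None,
    symmetrize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-edge flow and per-region burden differences between two models.

    Returns ``(edges, regions)``: an edge list (source, target, flow_a,
    flow_b, difference) over connected pairs, and a per-region burden table
    (burden_a, burden_b, difference). Sign convention: positive difference
    means model A exceeds model B, matching the blue (A > B) / magenta
    (A < B) split of flow-map renderings.
    """
    f_a = edge_flow(conn, u, params_a, x_a, u2=u2, symmetrize=symmetrize)
    f_b = edge_flow(conn, u, params_b, x_b, u2=u2, symmetrize=symmetrize)
    C = (conn.weights + conn.weights.T) / 2 if symmetrize else conn.weights
    src, dst = np.nonzero(C)
    edges = pd.DataFrame({
        "source": [conn.region_ids[j] for j in dst],
        "target": [conn.region_ids[i] for i in src],
        "flow_a": f_a[src, dst],
        "flow_b": f_b[src, dst],
        "difference": f_a[src, dst] - f_b[src, dst],
    })
    regions = pd.DataFrame({
        "region": conn.region_ids,
        "burden_a": np.asarray(x_a, float),
        "burden_b": np.asarray(x_b, float),
        "difference": np.asarray(x_a, float) - np.asarray(x_b, float),
    })
    return edges, regions


def two_gene_fit(conn, u1, u2, data: PathologyData, global_fit: FitResult | None,
                 rng_seed=None, **kwargs) -> FitResult:
    """Additive two-modulator fit; see :func:`nexis.inference.fit_two_gene`."""
    return fit_two_gene(conn, u1, u2, data, global_fit, rng_seed=rng_seed, **kwargs)
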