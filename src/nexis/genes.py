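"""Build modulator vectors u from regional gene-expression tables.

Single genes are min-max normalized to [0, 1] before entering the model, so
the conductance factor (1 + b*u) spans [1, 1 + b] and fitted b values are
comparable across genes. The homeostatic-microglia signature is the first
principal component of eight homeostasis genes, sign-fixed so that high scores
mean high homeostatic expression.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.decomposition import PCA

from .datatypes import DegenerateGeneError, ExpressionTable, GeneVector

log = logging.getLogger(__name__)

#: Homeostatic-microglia signature genes (first principal component input).
HOMEOSTASIS_GENES = (
    "P2ry12", "Cx3cr1", "Fcrls", "Olfml3", "Hexb", "Siglech", "Sox5", "Jun",
)

#: Canonical dose-response sweep: expression scaled by 2^k for k in -3..4.
DOSE_EXPONENTS = tuple(range(-3, 5))


def normalize_gene(raw, name: str = "gene") -> GeneVector:
    """Min-max rescale a raw per-region expression vector to [0, 1].

    Idempotent on already-normalized input; a constant vector carries no
    regional information and raises :class:`DegenerateGeneError`.
    """
    v = raw.values if isinstance(raw, GeneVector) else np.asarray(raw, dtype=float).ravel()
    if isinstance(raw, GeneVector) and name == "gene":
        name = raw.name
    if not np.all(np.isfinite(v)):
        raise ValueError(f"gene {name!r} has non-finite values")
    lo, hi = float(v.min()), float(v.max())
    if hi - lo <= 0:
        raise DegenerateGeneError(f"gene {name!r} is constant across regions")
    return GeneVector((v - lo) / (hi - lo), name=name, normalized=True)


def homeostasis_pc1(table: ExpressionTable, genes=HOMEOSTASIS_GENES) -> GeneVector:
    """Regional scores on PC1 of the (column-standardized) gene submatrix.

    The sign of the component is chosen so the scores correlate positively
    with the mean standardized expression of the constituent genes — high
    score means high homeostatic-gene abundance — and the scores are then
    min-max normalized to [0, 1].
    """
    genes = tuple(genes)
    missing = [g for g in genes if g not in table.gene_names]
    if missing:
        raise KeyError(f"gene(s) missing from expression table: {missing}")
    X = np.column_stack([table.column(g) for g in genes])
    if X.shape[0] < 3:
        raise ValueError("PC1 signature needs at least 3 regions")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        flat = [g for g, s in zip(genes, sd) if s == 0]
        raise DegenerateGeneError(f"constant gene column(s): {flat}")
    Z = (X - X.mean(axis=0)) / sd
    scores = PCA(n_components=1, svd_solver="full").fit_transform(Z).ravel()
    consensus = Z.mean(axis=1)
    if np.corrcoef(scores, consensus)[0, 1] < 0:
        scores = -scores
    name = "homeostasis-PC1" if genes == HOMEOSTASIS_GENES else f"PC1({len(genes)} genes)"
    return normalize_gene(scores, name=name)


def scale_gene(u: GeneVector, log2_factor: int, allow_extreme: bool = False) -> GeneVector:
    """Multiply expression by 2**log2_factor to emulate knock-down/over-expression.

    The canonical sweep uses exponents -3..4; values outside need
    ``allow_extreme``. The result is deliberately NOT re-normalized — the
    departure from baseline scale is the experimental manipulation.
    """
    k = int(log2_factor)
    if not allow_extreme and not (min(DOSE_EXPONENTS) <= k <= max(DOSE_EXPONENTS)):
        raise ValueError(
            f"log2_factor {k} outside canonical range "
            f"[{min(DOSE_EXPONENTS)}, {max(DOSE_EXPONENTS)}]; pass allow_extreme=True"
        )
    factor = 2.0 ** k
    values = u.values * factor
    still_unit = u.normalized and k <= 0  # scaling down keeps values within [0, 1]
    if not still_unit:
        log.info("gene %r scaled by 2^%d leaves the [0, 1] range", u.name, k)
    return GeneVector(values, name=f"{u.name}*2^{k}" if k else u.name,
                      normalized=still_unit)
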