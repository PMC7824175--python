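"""Comparator gene-set selectors: variability-based (VAR/STB) and PPI degree.

These provide the simple baselines a GA-selected panel is judged against:
the most-variable genes, the least-variable ("stable") genes, and the most
connected genes of a protein-protein interaction network restricted to the
marker panel.
"""

from __future__ import annotations

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_formats import ExpressionMatrix, GeneSet

__all__ = [
    "standardized_variance",
    "select_by_variance",
    "select_by_degree",
]


def standardized_variance(
    expr: ExpressionMatrix,
    panel: GeneSet,
    *,
    method: str = "vst",
    lowess_frac: float = 0.5,
) -> dict[str, float]:
    """Per-gene variance scores over cells, restricted to the panel.

    ``method="vst"`` follows the variance-stabilizing idea used for
    highly-variable-gene calling: a lowess trend of log10 variance against
    log10 mean is fit across the panel, each gene's values are standardized
    by its trend-predicted standard deviation with clipping at sqrt(#cells),
    and the score is the variance of the standardized values.
    ``method="plain"`` returns the raw per-gene variance.
    """
    idx = expr.gene_index(panel)
    sub = expr.values[idx]
    n_cells = sub.shape[1]
    means = sub.mean(axis=1)
    variances = sub.var(axis=1, ddof=1) if n_cells > 1 else np.zeros(len(idx))
    if method == "plain":
        return dict(zip(panel, variances.astype(float)))
    if method != "vst":
        raise ValueError(f"unknown variance method {method!r}")

    scores = np.zeros(len(idx))
    positive = (means > 0) & (variances > 0)
    if positive.sum() >= 3:
        log_mean = np.log10(means[positive])
        log_var = np.log10(variances[positive])
        fitted = lowess(
            log_var, log_mean, frac=lowess_frac, return_sorted=False
        )
        expected_sd = np.sqrt(10.0**fitted)
        clip = np.sqrt(n_cells)
        z = (sub[positive] - means[positive, None]) / expected_sd[:, None]
        z = np.clip(z, -clip, clip)
        scores[positive] = z.var(axis=1, ddof=1)
    else:
        # too few genes for a trend: fall back to plain variance
        scores = variances.astype(float)
    return dict(zip(panel, scores.astype(float)))


def select_by_variance(
    expr: ExpressionMatrix,
    panel: GeneSet,
    n: int,
    direction: str = "most",
    *,
    method: str = "vst",
) -> GeneSet:
    """Top-n most- or least-variable panel genes by standardized variance.

    Ties are broken deterministically by gene name (ascending).
    """
    if n > len(panel):
        raise ValueError(f"n={n} exceeds panel size {len(panel)}")
    if direction not in ("most", "least"):
        raise ValueError("direction must be 'most' or 'least'")
    scores = standardized_variance(expr, panel, method=method)
    reverse = direction == "most"
    ranked = sorted(
        panel, key=lambda g: ((-scores[g]) if reverse else scores[g], g)
    )
    return GeneSet(names=ranked[:n])


def select_by_degree(
    edges: list[tuple[str, str]], panel: GeneSet, n: int
) -> GeneSet:
    """Top-n panel genes by panel-internal network degree.

    Degree counts distinct neighbours *within the panel*; genes absent from
    the edge list have degree 0.  Ties break by gene name (ascending).
    """
    if n > len(panel):
        raise ValueError(f"n={n} exceeds panel size {len(panel)}")
    members = set(panel)
    neighbours: dict[str, set[str]] = {g: set() for g in panel}
    for a, b in edges:
        if a in members and b in members and a != b:
            neighbours[a].add(b)
            neighbours[b].add(a)
    ranked = sorted(panel, key=lambda g: (-len(neighbours[g]), g))
    return GeneSet(names=ranked[:n])
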