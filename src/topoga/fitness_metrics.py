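"""The four mapping-fidelity metrics and their composite geometric mean.

All four compare a gene-subset score matrix N against the gold-standard
matrix M (full marker panel) and are minimized at N = M:

* s1 — root-mean-square deviation over all cell-bin entries (MCC units);
* s2 — 2 minus the mean per-cell Spearman rank correlation between the
  matching rows of M and N (dimensionless, in [1, 3] when defined);
* s3 — mean over cells of 2 minus the fraction of the gold best bin(s)
  recovered among the subset's top-k bins (in [1, 2]);
* s4 — mean Euclidean distance between the gold best bin and the subset
  best bin (geometry length units).

The composite fitness is the geometric mean of the four, with an epsilon
floor on s1 and s4 so the product stays strictly positive at the identity
subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .distmap_core import ScoreMatrix, top_k_bins
from .io_formats import Geometry

__all__ = [
    "FitnessVector",
    "AssignmentContext",
    "metric1_rmsd",
    "metric2_rank",
    "metric3_jaccard",
    "metric4_distance",
    "composite_fitness",
    "evaluate_fitness",
]

EPSILON = 1e-8
FITNESS_MODES = ("composite", "m1", "m2", "m3", "m4")


@dataclass(frozen=True)
class FitnessVector:
    """The four metric values plus their geometric mean (lower is fitter)."""

    s1: float
    s2: float
    s3: float
    s4: float
    composite: float

    def scalar(self, mode: str = "composite") -> float:
        """The objective value under a fitness mode (composite or m1..m4)."""
        if mode == "composite":
            return self.composite
        if mode in ("m1", "m2", "m3", "m4"):
            return getattr(self, "s" + mode[1])
        raise ValueError(f"unknown fitness mode {mode!r}")


class AssignmentContext:
    """Gold-standard mapping context shared by the rank/overlap/distance
    metrics: the gold score matrix, its per-cell best bin, precomputed row
    ranks, and the bin geometry."""

    def __init__(self, gold_scores: ScoreMatrix, geometry: Geometry,
                 gold_k: int = 1) -> None:
        if gold_scores.n_bins != geometry.n_bins:
            raise ValueError(
                f"gold scores have {gold_scores.n_bins} bins but geometry "
                f"has {geometry.n_bins}"
            )
        if gold_k < 1:
            raise ValueError("gold_k must be >= 1")
        self.gold_scores = gold_scores
        self.geometry = geometry
        self.gold_k = gold_k
        self.gold_top = top_k_bins(gold_scores, gold_k)  # cells x gold_k
        self.gold_best_bin = self.gold_top[:, 0]
        self.gold_ranks = rankdata(gold_scores.values, axis=1)
        # rows constant in M have undefined rank correlation
        self.gold_row_sd = self.gold_ranks.std(axis=1)


def _check_shapes(m: ScoreMatrix, n: ScoreMatrix) -> None:
    if m.values.shape != n.values.shape:
        raise ValueError(
            f"shape mismatch: gold {m.values.shape} vs subset {n.values.shape}"
        )


def metric1_rmsd(m: ScoreMatrix, n: ScoreMatrix, *, sqrt: bool = True) -> float:
    """RMSD between the two score matrices over all a = cells x bins entries.

    ``sqrt=False`` returns the plain mean squared deviation instead.
    """
    _check_shapes(m, n)
    msd = float(np.mean((m.values - n.values) ** 2))
    return float(np.sqrt(msd)) if sqrt else msd


def metric2_rank(
    m: ScoreMatrix,
    n: ScoreMatrix,
    *,
    aggregation: str = "mean",
    gold_ranks: np.ndarray | None = None,
) -> float:
    """2 minus the per-cell Spearman correlation of bin scores, aggregated
    over cells.

    Rank agreement between each cell's gold and subset score profiles
    weighs nearby bins consistently rather than penalising raw-score offsets.
    A cell whose scores are constant in exactly one matrix has undefined
    rank correlation and contributes the neutral value 0; constant in both
    matrices the rank profiles agree trivially and the cell contributes 1,
    so the identity subset attains s2 = 1 on any instance.
    """
    _check_shapes(m, n)
    rm = gold_ranks if gold_ranks is not None else rankdata(m.values, axis=1)
    rn = rankdata(n.values, axis=1)
    rm_c = rm - rm.mean(axis=1, keepdims=True)
    rn_c = rn - rn.mean(axis=1, keepdims=True)
    num = (rm_c * rn_c).sum(axis=1)
    sm = (rm_c**2).sum(axis=1)
    sn = (rn_c**2).sum(axis=1)
    denom = np.sqrt(sm * sn)
    corr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    corr = np.where((sm == 0) & (sn == 0), 1.0, corr)
    if aggregation == "mean":
        return float(2.0 - corr.mean())
    if aggregation == "sum":
        return float(2.0 - corr.sum())
    raise ValueError(f"unknown aggregation {aggregation!r}")


def metric3_jaccard(
    ctx: AssignmentContext, n: ScoreMatrix, k: int = 10
) -> float:
    """Mean over cells of 2 minus the recovered fraction of gold best bins.

    With the default single gold bin per cell this is 2 minus the hit rate
    of the gold best bin within the subset's top-k candidate bins.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_shapes(ctx.gold_scores, n)
    k = min(k, n.n_bins)
    topk = top_k_bins(n, k)  # cells x k
    hits = (
        (ctx.gold_top[:, :, None] == topk[:, None, :]).any(axis=2).sum(axis=1)
    ).astype(float)
    return float(np.mean(2.0 - hits / ctx.gold_top.shape[1]))


def metric4_distance(
    ctx: AssignmentContext, n: ScoreMatrix, *, aggregation: str = "mean"
) -> float:
    """Euclidean distance between the gold and subset best-predicted bins,
    averaged over cells (or summed with ``aggregation="sum"``)."""
    _check_shapes(ctx.gold_scores, n)
    sub_best = top_k_bins(n, 1)[:, 0]
    coords = ctx.geometry.coords
    d = np.linalg.norm(coords[ctx.gold_best_bin] - coords[sub_best], axis=1)
    if aggregation == "mean":
        return float(d.mean())
    if aggregation == "sum":
        return float(d.sum())
    raise ValueError(f"unknown aggregation {aggregation!r}")


def composite_fitness(
    s1: float, s2: float, s3: float, s4: float, epsilon: float = EPSILON
) -> FitnessVector:
    """Geometric mean of the four metrics with an epsilon floor on the two
    that vanish at the identity subset (s1, s4)."""
    for name, v in (("s1", s1), ("s2", s2), ("s3", s3), ("s4", s4)):
        if not np.isfinite(v):
            raise ValueError(f"metric {name} is not finite: {v}")
    s1f = max(s1, epsilon)
    s4f = max(s4, epsilon)
    composite = float((s1f * s2 * s3 * s4f) ** 0.25)
    return FitnessVector(s1=s1, s2=s2, s3=s3, s4=s4, composite=composite)


def evaluate_fitness(
    ctx: AssignmentContext,
    n: ScoreMatrix,
    *,
    k: int = 10,
    epsilon: float = EPSILON,
) -> FitnessVector:
    """Compute all four metrics of a subset mapping against the gold context
    and fold them into the composite.

    The subset top-k bin lists are sorted once and shared between the
    overlap and best-bin-distance metrics.
    """
    s1 = metric1_rmsd(ctx.gold_scores, n)
    s2 = metric2_rank(ctx.gold_scores, n, gold_ranks=ctx.gold_ranks)
    topk = top_k_bins(n, min(k, n.n_bins))
    hits = (
        (ctx.gold_top[:, :, None] == topk[:, None, :]).any(axis=2).sum(axis=1)
    ).astype(float)
    s3 = float(np.mean(2.0 - hits / ctx.gold_top.shape[1]))
    coords = ctx.geometry.coords
    s4 = float(
        np.linalg.norm(
            coords[ctx.gold_best_bin] - coords[topk[:, 0]], axis=1
        ).mean()
    )
    return composite_fitness(s1, s2, s3, s4, epsilon=epsilon)
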