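"""Quantile binarization of single cells and the MCC cell-to-bin mapping.

A cell is compared with every spatial bin of the reference atlas over a
chosen marker-gene panel: each cell-bin pair yields a 2x2 confusion table of
binary expression calls, summarised by the Matthews correlation coefficient
(MCC).  Mapping with the full marker panel gives the gold-standard score
matrix M that gene-subset mappings N try to reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import BinaryAtlas, ExpressionMatrix, GeneSet

__all__ = [
    "BinaryCells",
    "ScoreMatrix",
    "binarize_cells",
    "confusion_counts",
    "mcc",
    "map_cells",
    "mcc_scores",
    "top_k_bins",
]

DEFAULT_QUANTILE = 0.23


@dataclass
class BinaryCells:
    """Binarized single-cell expression, genes x cells in {0,1}."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    threshold_quantile: float = DEFAULT_QUANTILE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary cell values must be in {0,1}")
        self.values = self.values.astype(np.int8)
        if not 0.0 < self.threshold_quantile < 1.0:
            raise ValueError("threshold quantile must lie in (0, 1)")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def restrict(self, genes: GeneSet) -> "BinaryCells":
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [lookup[g] for g in genes]
        return BinaryCells(
            gene_ids=list(genes),
            cell_ids=self.cell_ids,
            values=self.values[idx],
            threshold_quantile=self.threshold_quantile,
        )


@dataclass
class ScoreMatrix:
    """Cells x bins MCC scores for one gene panel."""

    values: np.ndarray
    gene_set_used: GeneSet | None = None
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("score matrix must be 2-D (cells x bins)")
        if np.any(self.values < -1 - 1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("MCC scores must lie in [-1, 1]")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def binarize_cells(
    expr: ExpressionMatrix,
    genes: GeneSet | None = None,
    q: float = DEFAULT_QUANTILE,
    *,
    method: str = "linear",
    strict: bool = True,
) -> BinaryCells:
    """Binarize expression gene-wise at the q-quantile across cells.

    For each gene the threshold is the *q*-quantile of its values over all
    cells (``method`` is any numpy quantile interpolation rule; the default
    is linear / type-7).  An entry is called expressed (1) when it exceeds
    the threshold — strictly by default, ``>=`` with ``strict=False``.  The
    default quantile of 0.23 is the value established for this mapping task.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    if genes is None:
        genes = GeneSet(names=list(expr.gene_ids))
    idx = expr.gene_index(genes)
    sub = expr.values[idx]
    thresholds = np.quantile(sub, q, axis=1, method=method)[:, None]
    binary = (sub > thresholds) if strict else (sub >= thresholds)
    return BinaryCells(
        gene_ids=list(genes),
        cell_ids=list(expr.cell_ids),
        values=binary.astype(np.int8),
        threshold_quantile=q,
    )


def confusion_counts(
    cell_vec: np.ndarray, bin_vec: np.ndarray
) -> tuple[int, int, int, int]:
    """2x2 confusion counts (TP, FP, FN, TN) of two binary gene vectors.

    The cell vector plays the role of the prediction and the bin vector the
    reference: TP counts genes called in both, FP cell-only, FN bin-only,
    TN neither.
    """
    cell_vec = np.asarray(cell_vec)
    bin_vec = np.asarray(bin_vec)
    if cell_vec.shape != bin_vec.shape:
        raise ValueError(
            f"length mismatch: {cell_vec.shape} vs {bin_vec.shape}"
        )
    if cell_vec.size < 1:
        raise ValueError("vectors must have length >= 1")
    tp = int(np.sum((cell_vec == 1) & (bin_vec == 1)))
    fp = int(np.sum((cell_vec == 1) & (bin_vec == 0)))
    fn = int(np.sum((cell_vec == 0) & (bin_vec == 1)))
    tn = int(np.sum((cell_vec == 0) & (bin_vec == 0)))
    return tp, fp, fn, tn


def mcc(tp: float, fp: float, fn: float, tn: float) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fp + fn + tn < 1:
        raise ValueError("confusion counts sum to zero")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def map_cells(
    cells: BinaryCells, atlas: BinaryAtlas, genes: GeneSet | None = None
) -> ScoreMatrix:
    """Score every cell against every bin by MCC over a gene panel.

    Restricting both the binarized cells and the atlas to *genes* (defaults
    to the full shared panel), the (cell, bin) entry is the MCC of the two
    binary gene vectors.  Computed via the closed form on vectorized
    confusion counts: with G panel genes, TP from a single integer matrix
    product and the other counts from the marginals.
    """
    if genes is None:
        genes = GeneSet(names=list(atlas.gene_ids))
    if len(genes) == 0:
        raise ValueError("empty gene set")
    cell_idx = {g: i for i, g in enumerate(cells.gene_ids)}
    atlas_idx = {g: i for i, g in enumerate(atlas.gene_ids)}
    for g in genes:
        if g not in cell_idx:
            raise KeyError(f"gene {g!r} missing from binarized cells")
        if g not in atlas_idx:
            raise KeyError(f"gene {g!r} missing from atlas")
    c = cells.values[[cell_idx[g] for g in genes]]  # G x C
    a = atlas.values[[atlas_idx[g] for g in genes]]  # G x B
    return ScoreMatrix(
        values=mcc_scores(c, a),
        gene_set_used=genes,
        cell_ids=list(cells.cell_ids),
    )


def mcc_scores(cell_matrix: np.ndarray, atlas_matrix: np.ndarray) -> np.ndarray:
    """Vectorized MCC kernel: binary genes x cells vs genes x bins arrays in,
    cells x bins score array out.  TP comes from one integer matrix product;
    FP/FN/TN follow from the per-cell and per-bin marginals."""
    # counts are small integers, exactly representable in float64; float
    # matmul routes through BLAS
    c = np.asarray(cell_matrix, dtype=np.float64)
    a = np.asarray(atlas_matrix, dtype=np.float64)
    if c.shape[0] != a.shape[0]:
        raise ValueError("cell and atlas matrices disagree on gene count")
    n_genes = c.shape[0]
    tp = c.T @ a  # cells x bins
    fp = c.sum(axis=0)[:, None] - tp
    fn = a.sum(axis=0)[None, :] - tp
    tn = n_genes - tp - fp - fn
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        return np.where(denom > 0, (tp * tn - fp * fn) / denom, 0.0)


def top_k_bins(scores: ScoreMatrix, k: int) -> np.ndarray:
    """Per-cell top-k bin indices, best first.

    Ties in score are broken deterministically by ascending bin index, which
    also makes the lists prefix-consistent across k.  Returns an integer
    array of shape (n_cells, k).
    """
    n_bins = scores.n_bins
    if not 1 <= k <= n_bins:
        raise ValueError(f"k must be in [1, {n_bins}], got {k}")
    # stable sort on negated scores keeps equal entries in original (i.e.
    # ascending bin-index) order, which is exactly the tie rule
    order = np.argsort(-scores.values, axis=1, kind="stable")
    return order[:, :k]
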