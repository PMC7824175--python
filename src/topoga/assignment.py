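"""Per-cell location assignment from an MCC score matrix.

Two strategies: the plain top-k highest-scoring bins, and the "best bin
plus nearest neighbours" rule — predict only the single highest-scoring bin
and fill the remaining k-1 slots with its geometrically nearest bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distmap_core import ScoreMatrix, top_k_bins
from .io_formats import Geometry

__all__ = ["AssignmentTable", "assign_topk", "assign_tn"]


@dataclass
class AssignmentTable:
    """Per-cell ordered lists of k predicted bin indices."""

    bins: np.ndarray  # cells x k, int
    strategy: str
    cell_ids: list[str] = field(default_factory=list)
    gene_set_used: object = None

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=int)
        if self.bins.ndim != 2:
            raise ValueError("assignment table must be 2-D (cells x k)")
        for i, row in enumerate(self.bins):
            if len(set(row.tolist())) != len(row):
                raise ValueError(f"duplicate bin in assignment row {i}")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(self.bins.shape[0])]

    @property
    def k(self) -> int:
        return self.bins.shape[1]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for cid, row in zip(self.cell_ids, self.bins):
                fh.write(cid + "\t" + "\t".join(str(int(b)) for b in row) + "\n")

    @classmethod
    def read(cls, path: str | Path, strategy: str = "unknown") -> "AssignmentTable":
        cell_ids, rows = [], []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            toks = line.split("\t")
            cell_ids.append(toks[0])
            rows.append([int(t) for t in toks[1:]])
        return cls(bins=np.asarray(rows), strategy=strategy, cell_ids=cell_ids)


def assign_topk(scores: ScoreMatrix, k: int = 10) -> AssignmentTable:
    """The k highest-scoring bins per cell, best first (score ties break by
    ascending bin index)."""
    return AssignmentTable(
        bins=top_k_bins(scores, k),
        strategy="mcc",
        cell_ids=list(scores.cell_ids),
        gene_set_used=scores.gene_set_used,
    )


def assign_tn(scores: ScoreMatrix, geom: Geometry, k: int = 10) -> AssignmentTable:
    """Best-scoring bin first, then its k-1 nearest bins by 3-D Euclidean
    distance (ascending distance, distance ties by ascending bin index).

    The best bin is excluded from its own neighbour list; positions 2..k
    depend only on the geometry given position 1.
    """
    n_bins = scores.n_bins
    if geom.n_bins != n_bins:
        raise ValueError(
            f"geometry has {geom.n_bins} bins but scores have {n_bins}"
        )
    if not 1 <= k <= n_bins:
        raise ValueError(f"k must be in [1, {n_bins}], got {k}")
    best = top_k_bins(scores, 1)[:, 0]
    coords = geom.coords
    idx = np.arange(n_bins)
    out = np.empty((scores.n_cells, k), dtype=int)
    # neighbour lists depend only on the best bin; cache per distinct bin
    neighbour_cache: dict[int, np.ndarray] = {}
    for i, b in enumerate(best):
        b = int(b)
        if b not in neighbour_cache:
            d = np.linalg.norm(coords - coords[b], axis=1)
            order = np.lexsort((idx, d))
            neighbour_cache[b] = order[order != b][: k - 1]
        out[i, 0] = b
        out[i, 1:] = neighbour_cache[b]
    return AssignmentTable(
        bins=out,
        strategy="tn",
        cell_ids=list(scores.cell_ids),
        gene_set_used=scores.gene_set_used,
    )
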