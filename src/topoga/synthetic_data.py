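"""Synthetic half-embryo instances for download-free testing.

Emulates the statistical structure the mapping method assumes: a 3-D cloud
of spatial bins on a half-ellipsoid surface, a binary reference atlas whose
informative genes follow smooth spatial patterns (axis gradients, pair-rule
style stripes, Gaussian blobs) alongside spatially uninformative decoys, and
single cells of known bin origin whose expression is negative-binomial with
dropout — the sparsity regime where only a fraction of genes yield counts in
any one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import BinaryAtlas, ExpressionMatrix, Geometry, write_atlas, \
    write_geometry, write_matrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "make_geometry",
    "make_atlas",
    "make_cells",
    "make_instance",
    "write_instance",
]

PATTERN_KINDS = ("gradient", "stripe", "blob")


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give a desk-scale half-embryo with
    moderate single-cell noise."""

    n_bins: int = 200
    n_cells: int = 300
    n_informative_genes: int = 20
    n_noise_genes: int = 20
    dropout_rate: float = 0.2
    flip_rate: float = 0.02
    pattern_kinds: tuple[str, ...] = PATTERN_KINDS
    seed: int = 0
    # negative-binomial emission: dispersion and on/off means chosen so the
    # default 0.23-quantile binarization separates the two states
    nb_size: float = 2.0
    mu_on: float = 10.0
    mu_off: float = 0.5
    noise_gene_rate: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 <= self.flip_rate < 1.0:
            raise ValueError("flip_rate must be in [0, 1)")
        for kind in self.pattern_kinds:
            if kind not in PATTERN_KINDS:
                raise ValueError(f"unknown pattern kind {kind!r}")
        if min(self.n_bins, self.n_cells, self.n_informative_genes) < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth withheld from the method: each cell's bin of origin and
    each gene's informativeness flag."""

    true_bins: np.ndarray  # per-cell bin index
    informative: dict[str, bool] = field(default_factory=dict)

    @property
    def informative_genes(self) -> list[str]:
        return [g for g, flag in self.informative.items() if flag]

    @property
    def noise_genes(self) -> list[str]:
        return [g for g, flag in self.informative.items() if not flag]


def make_geometry(cfg: SyntheticConfig, rng: np.random.Generator) -> Geometry:
    """Bins on the y >= 0 half of an ellipsoid surface, with jitter.

    The anterior-posterior axis (x) is the long axis, mirroring the
    half-embryo convention where only one side of the bilaterally symmetric
    cloud is kept.
    """
    n = cfg.n_bins
    # uniform-ish surface sampling via normalized Gaussians, then y folded
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts[:, 1] = np.abs(pts[:, 1])  # half-embryo: y >= 0
    semi_axes = np.array([2.0, 1.0, 1.0])  # elongated along x
    coords = pts * semi_axes
    coords += rng.normal(scale=0.02, size=coords.shape)
    coords[:, 1] = np.abs(coords[:, 1])
    return Geometry(coords=coords)


def _pattern_field(
    kind: str, coords: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    if kind == "gradient":
        axis = coords[:, int(rng.integers(3))]
        direction = rng.choice((-1.0, 1.0))
        return direction * axis + rng.normal(scale=0.05, size=len(axis))
    if kind == "stripe":
        n_stripes = int(rng.integers(2, 6))
        span = x.max() - x.min()
        phase = rng.uniform(0, 2 * np.pi)
        return np.sin(2 * np.pi * n_stripes * (x - x.min()) / span + phase)
    if kind == "blob":
        center = coords[int(rng.integers(len(coords)))]
        width = rng.uniform(0.5, 1.2)
        d2 = ((coords - center) ** 2).sum(axis=1)
        return np.exp(-d2 / (2 * width**2))
    raise ValueError(f"unknown pattern kind {kind!r}")


def make_atlas(
    cfg: SyntheticConfig, geom: Geometry, rng: np.random.Generator
) -> tuple[BinaryAtlas, dict[str, bool]]:
    """Binary reference atlas over the synthetic geometry.

    Informative genes threshold a smooth spatial field at a random quantile
    so each has between 10% and 90% positive bins; noise genes are i.i.d.
    Bernoulli draws with no spatial structure.
    """
    rows, gene_ids, flags = [], [], {}
    for i in range(cfg.n_informative_genes):
        kind = cfg.pattern_kinds[i % len(cfg.pattern_kinds)]
        fieldvals = _pattern_field(kind, geom.coords, rng)
        q = rng.uniform(0.1, 0.9)
        thr = np.quantile(fieldvals, q)
        binary = (fieldvals > thr).astype(np.int8)
        frac = binary.mean()
        if not 0.1 <= frac <= 0.9:  # re-threshold at median if degenerate
            binary = (fieldvals > np.median(fieldvals)).astype(np.int8)
        name = f"info_{kind}_{i:03d}"
        rows.append(binary)
        gene_ids.append(name)
        flags[name] = True
    for j in range(cfg.n_noise_genes):
        name = f"noise_{j:03d}"
        rows.append(
            (rng.random(cfg.n_bins) < cfg.noise_gene_rate).astype(np.int8)
        )
        gene_ids.append(name)
        flags[name] = False
    atlas = BinaryAtlas(gene_ids=gene_ids, values=np.vstack(rows))
    return atlas, flags


def make_cells(
    cfg: SyntheticConfig,
    atlas: BinaryAtlas,
    rng: np.random.Generator,
    informative: dict[str, bool] | None = None,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Cells sampled uniformly from bins, with noisy count emission.

    Each cell copies its bin's binary atlas column, corrupts it with
    state flips at ``flip_rate``, emits negative-binomial counts (mean
    ``mu_on`` where the latent state is 1, ``mu_off`` where 0, dispersion
    ``nb_size``), and finally zeroes entries with probability
    ``dropout_rate``.

    Genes flagged non-informative are true decoys: their latent state is
    re-drawn i.i.d. Bernoulli(``noise_gene_rate``) per cell, independent of
    the cell's bin, so they carry no positional signal even though the
    atlas shows an (unstructured) pattern for them.  With ``informative``
    omitted every gene follows its atlas column.
    """
    n_genes, n_bins = atlas.values.shape
    true_bins = rng.integers(n_bins, size=cfg.n_cells)
    latent = atlas.values[:, true_bins].astype(np.int8)  # genes x cells
    if informative is not None:
        decoy_rows = [
            i for i, g in enumerate(atlas.gene_ids) if not informative[g]
        ]
        if decoy_rows:
            latent[decoy_rows] = (
                rng.random((len(decoy_rows), cfg.n_cells))
                < cfg.noise_gene_rate
            ).astype(np.int8)
    flips = rng.random(latent.shape) < cfg.flip_rate
    latent = np.where(flips, 1 - latent, latent)
    mu = np.where(latent == 1, cfg.mu_on, cfg.mu_off)
    p = cfg.nb_size / (cfg.nb_size + mu)
    counts = rng.negative_binomial(cfg.nb_size, p).astype(float)
    dropped = rng.random(counts.shape) < cfg.dropout_rate
    counts[dropped] = 0.0
    expr = ExpressionMatrix(
        gene_ids=list(atlas.gene_ids),
        cell_ids=[f"cell_{i:04d}" for i in range(cfg.n_cells)],
        values=counts,
    )
    return expr, true_bins


def make_instance(
    cfg: SyntheticConfig,
) -> tuple[BinaryAtlas, Geometry, ExpressionMatrix, SyntheticTruth]:
    """Full synthetic trio (atlas, geometry, cells) plus the ground truth."""
    rng = np.random.default_rng(cfg.seed)
    geom = make_geometry(cfg, rng)
    atlas, flags = make_atlas(cfg, geom, rng)
    expr, true_bins = make_cells(cfg, atlas, rng, informative=flags)
    truth = SyntheticTruth(true_bins=true_bins, informative=flags)
    return atlas, geom, expr, truth


def write_instance(
    cfg: SyntheticConfig, out_dir: str | Path
) -> tuple[BinaryAtlas, Geometry, ExpressionMatrix, SyntheticTruth]:
    """Generate an instance and write atlas.tsv, geometry.tsv, dge.tsv and
    truth.tsv into *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas, geom, expr, truth = make_instance(cfg)
    write_atlas(atlas, out / "atlas.tsv")
    write_geometry(geom, out / "geometry.tsv")
    write_matrix(expr, out / "dge.tsv")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("cell_id\ttrue_bin\n")
        for cid, b in zip(expr.cell_ids, truth.true_bins):
            fh.write(f"{cid}\t{int(b)}\n")
    with open(out / "gene_flags.tsv", "w") as fh:
        fh.write("gene_id\tinformative\n")
        for g, flag in truth.informative.items():
            fh.write(f"{g}\t{int(flag)}\n")
    return atlas, geom, expr, truth
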