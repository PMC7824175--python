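"""High-level workflows: the multi-size selection pipeline, selector
comparison with bootstrap, and reproducible run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .assignment import AssignmentTable, assign_tn, assign_topk
from .baseline_selectors import select_by_degree, select_by_variance
from .distmap_core import BinaryCells, ScoreMatrix, binarize_cells, map_cells, \
    top_k_bins
from .enrichment import AnnotationMap, prioritize_by_overlap
from .fitness_metrics import AssignmentContext, FitnessVector, composite_fitness
from .ga_selector import GAConfig, SubsetEvaluator, evolve
from .io_formats import BinaryAtlas, ExpressionMatrix, GeneSet, Geometry, \
    write_gene_set

__all__ = [
    "RunManifest",
    "build_evaluator",
    "per_cell_metrics",
    "bootstrap_fitness",
    "run_challenge_pipeline",
    "run_comparison",
]


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit: the command, the
    resolved configuration, the seed, and digests of the input files."""

    command: str
    config: dict
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    tool_version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    @classmethod
    def create(
        cls, command: str, config: dict, seed: int,
        inputs: dict[str, str | Path] | None = None,
    ) -> "RunManifest":
        digests = {
            name: _digest(p) for name, p in (inputs or {}).items()
            if Path(p).exists()
        }
        return cls(command=command, config=config, seed=seed,
                   input_digests=digests)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
            + "\n"
        )

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def build_evaluator(
    atlas: BinaryAtlas,
    geom: Geometry,
    expr: ExpressionMatrix,
    *,
    quantile: float = 0.23,
    top_k: int = 10,
) -> SubsetEvaluator:
    """Binarize cells on the full atlas panel, compute the gold-standard
    score matrix, and wrap both in a subset evaluator."""
    panel = GeneSet(names=list(atlas.gene_ids))
    cells = binarize_cells(expr, panel, q=quantile)
    gold = map_cells(cells, atlas, panel)
    ctx = AssignmentContext(gold, geom)
    return SubsetEvaluator(cells, atlas, ctx, top_k=top_k)


def per_cell_metrics(
    ctx: AssignmentContext,
    n: ScoreMatrix,
    *,
    k: int = 10,
    assigned: AssignmentTable | None = None,
) -> dict[str, np.ndarray]:
    """Per-cell contributions to the four metrics, for bootstrap aggregation.

    ``assigned`` overrides the top-k candidate lists used by the overlap
    metric (e.g. a best-bin-plus-neighbours table); the best-bin distance
    always uses the score argmax.
    """
    m = ctx.gold_scores.values
    nv = n.values
    sq = ((m - nv) ** 2).mean(axis=1)
    from scipy.stats import rankdata

    rm = ctx.gold_ranks
    rn = rankdata(nv, axis=1)
    rm_c = rm - rm.mean(axis=1, keepdims=True)
    rn_c = rn - rn.mean(axis=1, keepdims=True)
    sm = (rm_c**2).sum(axis=1)
    sn = (rn_c**2).sum(axis=1)
    denom = np.sqrt(sm * sn)
    corr = np.where(
        denom > 0, (rm_c * rn_c).sum(axis=1) / np.where(denom > 0, denom, 1.0),
        0.0,
    )
    corr = np.where((sm == 0) & (sn == 0), 1.0, corr)
    topk = assigned.bins if assigned is not None else top_k_bins(n, k)
    hit = (
        (ctx.gold_top[:, :, None] == topk[:, None, :]).any(axis=2).sum(axis=1)
        / ctx.gold_top.shape[1]
    ).astype(float)
    sub_best = top_k_bins(n, 1)[:, 0]
    coords = ctx.geometry.coords
    dist = np.linalg.norm(coords[ctx.gold_best_bin] - coords[sub_best], axis=1)
    return {"sq": sq, "corr": corr, "hit": hit, "dist": dist}


def _fold(parts: dict[str, np.ndarray], idx: np.ndarray) -> FitnessVector:
    s1 = float(np.sqrt(parts["sq"][idx].mean()))
    s2 = float(2.0 - parts["corr"][idx].mean())
    s3 = float(np.mean(2.0 - parts["hit"][idx]))
    s4 = float(parts["dist"][idx].mean())
    return composite_fitness(s1, s2, s3, s4)


def bootstrap_fitness(
    ctx: AssignmentContext,
    n: ScoreMatrix,
    *,
    k: int = 10,
    assigned: AssignmentTable | None = None,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, float]]:
    """Mean and standard deviation of each metric under bootstrap resampling
    of cells (with replacement)."""
    if rng is None:
        rng = np.random.default_rng(0)
    parts = per_cell_metrics(ctx, n, k=k, assigned=assigned)
    n_cells = n.n_cells
    draws = {"s1": [], "s2": [], "s3": [], "s4": [], "composite": []}
    for _ in range(max(1, n_boot)):
        idx = rng.integers(n_cells, size=n_cells)
        fv = _fold(parts, idx)
        for name in draws:
            draws[name].append(getattr(fv, name) if name != "composite"
                               else fv.composite)
    point = _fold(parts, np.arange(n_cells))
    out = {}
    for name, vals in draws.items():
        arr = np.asarray(vals)
        out[name] = {
            "value": getattr(point, name) if name != "composite"
            else point.composite,
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=0)) if n_boot > 1 else 0.0,
        }
    return out


def run_challenge_pipeline(
    atlas: BinaryAtlas,
    geom: Geometry,
    expr: ExpressionMatrix,
    *,
    sizes: tuple[int, ...] = (60, 40, 20),
    ga_config: GAConfig | None = None,
    annotation: AnnotationMap | None = None,
    strategy: str = "mcc",
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> dict[int, dict]:
    """Select a gene subset of each requested size and assign locations.

    Per size: evolve the GA, take the last three unique best sets, re-rank
    them by annotation-term overlap with the full driver panel when an
    annotation map is available (otherwise the best-fitness set is kept),
    then produce the location assignment under the chosen strategy.
    """
    evaluator = build_evaluator(atlas, geom, expr)
    driver = GeneSet(names=list(atlas.gene_ids))
    results: dict[int, dict] = {}
    base = ga_config or GAConfig()
    for n in sizes:
        cfg = dataclasses.replace(base, n=n, seed=seed)
        trace = evolve(evaluator, cfg)
        candidates = trace.last_unique_best(3)
        cand_sets = [evaluator.gene_set(c) for c in candidates]
        cand_fit = [c.fitness.scalar(cfg.fitness_mode) for c in candidates]
        if annotation is not None:
            chosen = prioritize_by_overlap(
                cand_sets, driver, annotation, fitness=cand_fit
            )
        else:
            chosen = cand_sets[0]
        scores = map_cells(
            binarize_cells(expr, chosen), atlas, chosen
        )
        k = min(evaluator.top_k, scores.n_bins)
        table = (
            assign_tn(scores, geom, k=k)
            if strategy == "tn"
            else assign_topk(scores, k=k)
        )
        results[n] = {
            "gene_set": chosen,
            "trace": trace,
            "assignment": table,
            "candidates": cand_sets,
        }
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_gene_set(chosen, out / f"genes_n{n}.txt")
            table.write(out / f"assignment_n{n}.tsv")
            with open(out / f"trace_n{n}.tsv", "w") as fh:
                fh.write("generation\tbest_fitness\ts1\ts2\ts3\ts4\n")
                for g, (bf, fv) in enumerate(
                    zip(trace.best_fitness, trace.best_vectors)
                ):
                    fh.write(
                        f"{g}\t{bf:.8g}\t{fv.s1:.8g}\t{fv.s2:.8g}"
                        f"\t{fv.s3:.8g}\t{fv.s4:.8g}\n"
                    )
            manifest = RunManifest.create(
                "select", dataclasses.asdict(cfg), seed
            )
            manifest.write(out / f"manifest_n{n}.json")
    return results


def run_comparison(
    atlas: BinaryAtlas,
    geom: Geometry,
    expr: ExpressionMatrix,
    *,
    n: int,
    ga_config: GAConfig | None = None,
    edges: list[tuple[str, str]] | None = None,
    strategies: tuple[str, ...] = ("mcc", "tn"),
    n_boot: int = 1000,
    seed: int = 0,
) -> list[dict]:
    """Score GA/VAR/STB/PPI selections under each assignment strategy.

    Returns one record per (selector, strategy) with bootstrap mean +- sd of
    the four metrics and the composite.
    """
    evaluator = build_evaluator(atlas, geom, expr)
    panel = GeneSet(names=list(atlas.gene_ids))
    cfg = dataclasses.replace(ga_config or GAConfig(), n=n, seed=seed)
    trace = evolve(evaluator, cfg)
    selections: dict[str, GeneSet] = {
        "GA": evaluator.gene_set(trace.best),
        "VAR": select_by_variance(expr, panel, n, "most"),
        "STB": select_by_variance(expr, panel, n, "least"),
    }
    if edges is not None:
        selections["PPI"] = select_by_degree(edges, panel, n)
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for method, genes in selections.items():
        scores = map_cells(binarize_cells(expr, genes), atlas, genes)
        k = min(evaluator.top_k, scores.n_bins)
        for strat in strategies:
            assigned = (
                assign_tn(scores, geom, k=k) if strat == "tn" else None
            )
            stats = bootstrap_fitness(
                evaluator.ctx, scores, k=k, assigned=assigned,
                n_boot=n_boot, rng=rng,
            )
            rows.append(
                {"method": method, "strategy": strat, "genes": genes,
                 "stats": stats}
            )
    return rows
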