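"""Annotation-term enrichment and overlap-based re-prioritization.

A data-driven gene subset is not guaranteed to be biologically coherent, so
the final candidate sets from a GA run are re-ranked by how well their
enriched annotation terms (one-sided hypergeometric over-representation,
Benjamini-Hochberg corrected) overlap those of the full driver panel.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import false_discovery_control, hypergeom

from .io_formats import GeneSet

__all__ = ["AnnotationMap", "hypergeom_enrich", "prioritize_by_overlap"]


@dataclass
class AnnotationMap:
    """term_id -> annotated gene names, within a stated gene universe."""

    terms: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty annotation universe")
        cleaned = {}
        for term, genes in self.terms.items():
            members = set(genes) & self.universe
            if members:
                cleaned[term] = members
        self.terms = cleaned


def hypergeom_enrich(
    genes: GeneSet,
    ann: AnnotationMap,
    alpha: float = 0.05,
    *,
    return_pvalues: bool = False,
):
    """Terms over-represented in *genes* at BH-adjusted p <= alpha.

    For each term the raw p-value is the upper tail of the hypergeometric
    distribution: the probability of drawing at least the observed overlap
    when |genes| names are drawn from the universe without replacement.
    """
    query = set(genes) & ann.universe
    missing = set(genes) - ann.universe
    if missing:
        raise ValueError(
            f"genes outside annotation universe: {sorted(missing)[:5]}"
        )
    m = len(ann.universe)
    n_draw = len(query)
    term_ids = sorted(ann.terms)
    raw = []
    for term in term_ids:
        members = ann.terms[term]
        overlap = len(query & members)
        # P(X >= overlap), X ~ Hypergeom(M=universe, n=term size, N=draw)
        raw.append(float(hypergeom.sf(overlap - 1, m, len(members), n_draw)))
    if not term_ids:
        return ({}, {}) if return_pvalues else set()
    adjusted = false_discovery_control(raw, method="bh")
    enriched = {
        t for t, p_adj in zip(term_ids, adjusted) if p_adj <= alpha
    }
    if return_pvalues:
        return (
            dict(zip(term_ids, raw)),
            dict(zip(term_ids, adjusted)),
        )
    return enriched


def prioritize_by_overlap(
    candidates: list[GeneSet],
    driver: GeneSet,
    ann: AnnotationMap,
    alpha: float = 0.05,
    fitness: list[float] | None = None,
) -> GeneSet:
    """Pick the candidate whose enriched terms overlap the driver panel's
    enriched terms the most.

    Ties go to the candidate with the better (lower) fitness when given,
    then to the earliest candidate in input order.
    """
    if not candidates:
        raise ValueError("no candidate gene sets")
    driver_terms = hypergeom_enrich(driver, ann, alpha)
    best_i = 0
    best_overlap = -1
    for i, cand in enumerate(candidates):
        overlap = len(hypergeom_enrich(cand, ann, alpha) & driver_terms)
        better = overlap > best_overlap
        if overlap == best_overlap and fitness is not None:
            better = fitness[i] < fitness[best_i]
        if better:
            best_i, best_overlap = i, overlap
    return candidates[best_i]
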