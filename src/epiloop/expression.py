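"""Condition-specific gene calling, expression breadth, and promoter RNAPII binding.

The specificity call is a declared threshold rule on fold change and
abundance, not a fitted differential-expression model: with pseudocount c,
``log2fc = log2((mean_a + c) / (mean_b + c))`` and a gene is A-specific when
``log2fc >= log2fc_min`` and ``mean_a >= min_level`` (B symmetric); genes
below ``min_level`` in both states are low-expressed, everything else is
shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomicIndex, tss_window
from .types import ExpressionTable, GeneModel, Peak


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2fc: float
    mean_a: float
    mean_b: float
    call: str  # a_specific | b_specific | shared | low_expressed


@dataclass(frozen=True)
class BreadthResult:
    gene_id: str
    n_expressed: int
    breadth: float
    cell_specific: bool


def call_condition_specific_genes(
    expr_a: ExpressionTable,
    expr_b: ExpressionTable,
    log2fc_min: float = 2.0,
    min_level: float = 1.0,
    pseudocount: float = 0.1,
) -> list[DEResult]:
    """Call A-specific / B-specific / shared / low-expressed genes.

    Both tables must share the same gene universe; a gene present in only
    one state is an error rather than a silent drop.
    """
    genes_a, genes_b = set(expr_a.genes), set(expr_b.genes)
    if genes_a != genes_b:
        odd = sorted(genes_a.symmetric_difference(genes_b))[:5]
        raise ValueError(f"expression tables do not share gene universe, e.g. {odd}")
    mean_a = expr_a.frame.mean(axis=1)
    mean_b = expr_b.frame.reindex(expr_a.frame.index).mean(axis=1)
    results = []
    for gene_id in expr_a.genes:
        ma, mb = float(mean_a[gene_id]), float(mean_b[gene_id])
        log2fc = float(np.log2((ma + pseudocount) / (mb + pseudocount)))
        if log2fc >= log2fc_min and ma >= min_level:
            call = "a_specific"
        elif -log2fc >= log2fc_min and mb >= min_level:
            call = "b_specific"
        elif ma < min_level and mb < min_level:
            call = "low_expressed"
        else:
            call = "shared"
        results.append(DEResult(gene_id, log2fc, ma, mb, call))
    return results


def expression_breadth(
    panel: ExpressionTable,
    threshold: float = 1.0,
    breadth_max: float = 0.2,
) -> list[BreadthResult]:
    """Fraction of panel cells in which each gene is expressed.

    A gene is labeled cell-specific when its breadth is <= ``breadth_max``.
    """
    if len(panel.genes) < 1:
        raise ValueError("panel must contain at least one gene")
    n_cells = len(panel.samples)
    expressed = (panel.frame.to_numpy() >= threshold).sum(axis=1)
    return [
        BreadthResult(g, int(k), k / n_cells, bool(k / n_cells <= breadth_max))
        for g, k in zip(panel.genes, expressed)
    ]


def promoter_binding_fraction(
    genes: Sequence[GeneModel],
    peaks: Sequence[Peak],
    flank: int = 2000,
) -> tuple[dict[str, bool], float]:
    """Per-gene promoter occupancy by a single-factor peak set.

    A gene is bound iff >= 1 peak overlaps its TSS +/- flank window;
    returns the per-gene booleans and the bound fraction.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    factors = {p.factor for p in peaks}
    if len(factors) > 1:
        raise ValueError(f"peaks must be of a single factor (got {sorted(factors)})")
    index = GenomicIndex((p.region, True) for p in peaks)
    bound = {g.gene_id: index.any_overlap(tss_window(g, flank)) for g in genes}
    return bound, sum(bound.values()) / len(genes)
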