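"""Enhancer chromatin states, promoter strength, anchor annotation, E-P network.

Enhancer states follow the histone-mark co-occurrence rules: active
(H3K4me1 + H3K27ac), intermediate (H3K4me1 only), poised (H3K4me1 +
H3K27me3); regions without H3K4me1 are unclassified.  Promoter strength is
the log2 ratio of H3K4me3 to H3K4me1 mean signal in the promoter window:
negative = enhancer-like (Ep), non-negative = strong.  The enhancer
universe is H3K4me1 peaks outside all promoter windows that overlap a
RNAPII loop anchor, so only enhancers engaged in looping enter the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

from .intervals import GenomicIndex, SignalTrack, overlaps, tss_window
from .stats import wilcoxon_rank_sum
from .types import ExpressionTable, GeneModel, GenomicInterval, Loop, Peak

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegulatoryElement:
    region: GenomicInterval
    kind: str  # enhancer | promoter
    state: str  # active | intermediate | poised | unclassified (enhancers)
    marks: frozenset[str] = frozenset()

    @property
    def element_id(self) -> str:
        return f"{self.kind}:{self.region.chrom}:{self.region.start}-{self.region.end}"


@dataclass(frozen=True)
class PromoterStrength:
    gene_id: str
    me3_signal: float
    me1_signal: float
    log2_ratio: float
    klass: str  # strong | enhancer_like


def classify_enhancer_state(marks: set[str] | frozenset[str]) -> str:
    """Map a histone-mark combination to an enhancer chromatin state."""
    if "H3K4me1" not in marks:
        return "unclassified"
    if "H3K27ac" in marks:
        return "active"
    if "H3K27me3" in marks:
        return "poised"
    return "intermediate"


def promoter_strength_score(
    gene: GeneModel,
    me3_track: SignalTrack,
    me1_track: SignalTrack,
    flank: int = 2000,
    eps: float = 0.1,
) -> PromoterStrength:
    """Score a promoter as strong vs enhancer-like from the me3/me1 ratio.

    Ties at exactly 0 classify as strong (the boundary carries no measure
    after eps-smoothing).
    """
    window = tss_window(gene, flank)
    me3 = me3_track.mean_in(window)
    me1 = me1_track.mean_in(window)
    ratio = float(np.log2((me3 + eps) / (me1 + eps)))
    klass = "enhancer_like" if ratio < 0 else "strong"
    return PromoterStrength(gene.gene_id, me3, me1, ratio, klass)


def build_enhancer_elements(
    k4me1_peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    rnapii_loops: Sequence[Loop],
    other_marks: Mapping[str, Sequence[Peak]] | None = None,
    flank: int = 2000,
    require_anchor_overlap: bool = True,
) -> list[RegulatoryElement]:
    """Define the enhancer universe and classify each element's state.

    H3K4me1 peaks outside every promoter window, intersected (by default)
    with RNAPII loop anchors; ``require_anchor_overlap=False`` keeps all
    distal H3K4me1 peaks instead.
    """
    tss_index = GenomicIndex((tss_window(g, flank), g.gene_id) for g in genes)
    anchor_index = GenomicIndex()
    for lp in rnapii_loops:
        anchor_index.add(lp.anchor_a, True)
        anchor_index.add(lp.anchor_b, True)
    mark_indexes = {
        mark: GenomicIndex((p.region, True) for p in peaks)
        for mark, peaks in (other_marks or {}).items()
    }
    elements = []
    for p in k4me1_peaks:
        if tss_index.any_overlap(p.region):
            continue
        if require_anchor_overlap and not anchor_index.any_overlap(p.region):
            continue
        marks = {"H3K4me1"}
        for mark, idx in mark_indexes.items():
            if idx.any_overlap(p.region):
                marks.add(mark)
        elements.append(
            RegulatoryElement(
                region=p.region,
                kind="enhancer",
                state=classify_enhancer_state(marks),
                marks=frozenset(marks),
            )
        )
    elements.sort(key=lambda e: (e.region.chrom, e.region.start, e.region.end))
    return elements


@dataclass(frozen=True)
class AnchorAnnotation:
    label: str  # P | Ep | E | none
    gene_id: str | None = None
    element: RegulatoryElement | None = None

    @property
    def node(self) -> Hashable | None:
        if self.label in ("P", "Ep"):
            return ("P", self.gene_id)
        if self.label == "E":
            return ("E", self.element.element_id)
        return None


class AnchorAnnotator:
    """Annotate loop anchors as P / Ep / E / none.

    Promoter identity has precedence over enhancer; an anchor overlapping
    several promoter windows is annotated with the nearest TSS (logged).
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        strengths: Mapping[str, PromoterStrength],
        enhancers: Sequence[RegulatoryElement],
        flank: int = 2000,
    ):
        self._genes = {g.gene_id: g for g in genes}
        self._strengths = dict(strengths)
        self._tss_index = GenomicIndex(
            (tss_window(g, flank), g.gene_id) for g in genes
        )
        self._enh_index = GenomicIndex((e.region, e) for e in enhancers)

    def annotate(self, anchor: GenomicInterval) -> AnchorAnnotation:
        gene_hits = self._tss_index.query(anchor)
        if gene_hits:
            if len(gene_hits) > 1:
                log.debug(
                    "anchor %s:%d-%d overlaps %d promoter windows; taking nearest",
                    anchor.chrom, anchor.start, anchor.end, len(gene_hits),
                )
            gid = min(
                gene_hits,
                key=lambda gid: (abs(self._genes[gid].tss - anchor.midpoint), gid),
            )
            klass = self._strengths.get(gid)
            label = "Ep" if klass is not None and klass.klass == "enhancer_like" else "P"
            return AnchorAnnotation(label, gene_id=gid)
        enh_hits = self._enh_index.query(anchor)
        if enh_hits:
            best = min(
                enh_hits,
                key=lambda e: (abs(e.region.midpoint - anchor.midpoint), e.element_id),
            )
            return AnchorAnnotation("E", element=best)
        return AnchorAnnotation("none")


@dataclass
class EPEdge:
    node_a: Hashable
    node_b: Hashable
    label_a: str  # P | Ep | E, aligned with node_a
    label_b: str
    edge_type: str  # E-P | Ep-P | P-P | E-E | E-Ep | Ep-Ep
    gene_ids: tuple[str, ...]
    loop_indices: list[int]


@dataclass
class EPNetwork:
    edges: list[EPEdge]
    enhancer_counts: dict[str, int]  # gene -> distinct E/Ep partners

    @property
    def n_edges(self) -> int:
        return len(self.edges)


_EDGE_TYPE = {
    frozenset(["P"]): "P-P",
    frozenset(["P", "Ep"]): "Ep-P",
    frozenset(["Ep"]): "Ep-Ep",
    frozenset(["P", "E"]): "E-P",
    frozenset(["Ep", "E"]): "E-Ep",
    frozenset(["E"]): "E-E",
}


def build_ep_network(
    loops: Sequence[Loop],
    annotator: AnchorAnnotator,
) -> EPNetwork:
    """Collapse annotated loops into a typed element-level network.

    One edge per unordered (element, element) pair; loops with a 'none'
    anchor or joining an element to itself contribute no edge.  A gene's
    connected-enhancer count is its number of distinct E partners plus
    distinct partner genes with enhancer-like promoters.
    """
    edges: dict[tuple, EPEdge] = {}
    for i, lp in enumerate(loops):
        ann_a = annotator.annotate(lp.anchor_a)
        ann_b = annotator.annotate(lp.anchor_b)
        node_a, node_b = ann_a.node, ann_b.node
        if node_a is None or node_b is None or node_a == node_b:
            continue
        pairs = sorted(
            ((node_a, ann_a.label), (node_b, ann_b.label)), key=lambda t: repr(t[0])
        )
        key = (pairs[0][0], pairs[1][0])
        if key in edges:
            edges[key].loop_indices.append(i)
            continue
        labels = frozenset((ann_a.label, ann_b.label))
        gene_ids = tuple(
            sorted(a.gene_id for a in (ann_a, ann_b) if a.gene_id is not None)
        )
        edges[key] = EPEdge(
            key[0], key[1], pairs[0][1], pairs[1][1], _EDGE_TYPE[labels], gene_ids, [i]
        )

    counts: dict[str, set] = {}
    for edge in edges.values():
        sides = (
            (edge.node_a, edge.label_a, edge.node_b, edge.label_b),
            (edge.node_b, edge.label_b, edge.node_a, edge.label_a),
        )
        for node, label, other, other_label in sides:
            if label not in ("P", "Ep"):
                continue
            gid = node[1]
            if other_label == "E":
                counts.setdefault(gid, set()).add(other)
            elif other_label == "Ep":
                # partner gene with enhancer-like promoter acts as an enhancer
                counts.setdefault(gid, set()).add(other)
    ordered = sorted(edges.values(), key=lambda e: (repr(e.node_a), repr(e.node_b)))
    return EPNetwork(ordered, {g: len(s) for g, s in counts.items()})


def enhancer_count_effect(
    network: EPNetwork,
    expr: Mapping[str, float],
    strata: Sequence[tuple[str, int, int | None]] = (
        ("1", 1, 1),
        ("2", 2, 2),
        (">=3", 3, None),
    ),
) -> dict:
    """Expression stratified by connected-enhancer count, with rank-sum p.

    ``strata`` rows are (label, lo, hi) on enhancer count (hi None =
    unbounded).  Returns per-stratum expression lists and pairwise
    two-sided rank-sum p-values (None when a stratum has < 2 genes).
    """
    groups: dict[str, list[float]] = {label: [] for label, _, _ in strata}
    for gene, count in network.enhancer_counts.items():
        if gene not in expr:
            continue
        for label, lo, hi in strata:
            if count >= lo and (hi is None or count <= hi):
                groups[label].append(float(expr[gene]))
                break
    nonempty = [lab for lab in groups if groups[lab]]
    if len(nonempty) < 2:
        raise ValueError("need >= 2 non-empty strata")
    pvalues: dict[tuple[str, str], float | None] = {}
    labels = [label for label, _, _ in strata]
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            if len(groups[la]) < 2 or len(groups[lb]) < 2:
                pvalues[(la, lb)] = None
                continue
            _, p = wilcoxon_rank_sum(groups[la], groups[lb])
            pvalues[(la, lb)] = p
    medians = {
        lab: (float(np.median(v)) if v else None) for lab, v in groups.items()
    }
    return {"groups": groups, "medians": medians, "pvalues": pvalues}
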