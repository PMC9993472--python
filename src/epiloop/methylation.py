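"""Differential CTCF binding, binding breadth, and CpG methylation analyses.

Differential binding uses the MA representation on merged CTCF peak
footprints inside promoter windows: ``M = log2((ia + eps)/(ib + eps))``,
``A = 0.5 * log2((ia + eps)(ib + eps))``, call up_a when M >= m_min, up_b
when M <= -m_min, else common.  Region methylation is the coverage-weighted
mean beta of covered CpGs, at CTCF peak scale (~500 bp) or motif scale
(219 bp window).  DMCs are called per shared cytosine by Fisher exact on
the methylated/unmethylated count table with BH correction and an absolute
beta-difference gate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicIndex, merge_intervals, tss_window
from .stats import benjamini_hochberg, fisher_exact_2x2, ks_two_sample, wilcoxon_rank_sum
from .types import CpGRecord, GeneModel, GenomicInterval, Peak

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifferentialBindingSite:
    site: GenomicInterval
    intensity_a: float
    intensity_b: float
    M: float
    A: float
    call: str  # up_a | up_b | common
    nearest_gene: str | None


@dataclass(frozen=True)
class RegionMethylation:
    region: GenomicInterval
    level_kind: str  # peak_500bp | motif_219bp
    n_cpgs: int
    beta_mean: float  # nan when fewer than min_cpgs covered CpGs


@dataclass(frozen=True)
class DMC:
    chrom: str
    pos: int
    beta_a: float
    beta_b: float
    delta: float
    p_value: float
    q_value: float


def _max_intensity(site: GenomicInterval, index: GenomicIndex) -> float:
    hits = index.query(site)
    return max((h for h in hits), default=0.0)


def differential_binding(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    genes: Sequence[GeneModel],
    flank: int = 2000,
    m_min: float = 1.0,
    eps: float = 0.1,
) -> list[DifferentialBindingSite]:
    """MA-classify CTCF binding at promoter-proximal merged peak footprints.

    Sites are the merged footprints of the union of both states' peaks,
    restricted to the TSS windows of the supplied genes; the per-state
    intensity is the maximum overlapping peak intensity (0 when absent).
    """
    windows = [tss_window(g, flank) for g in genes]
    window_index = GenomicIndex((w, True) for w in windows)
    candidates = [
        p.region for p in list(peaks_a) + list(peaks_b)
        if window_index.any_overlap(p.region)
    ]
    if not candidates:
        log.warning("no CTCF peaks overlap the supplied promoter windows")
        return []
    sites = merge_intervals(candidates)
    index_a = GenomicIndex((p.region, p.intensity) for p in peaks_a)
    index_b = GenomicIndex((p.region, p.intensity) for p in peaks_b)
    tss_by_gene = [(g.gene_id, g.chrom, g.tss) for g in genes]
    out = []
    for site in sites:
        ia = _max_intensity(site, index_a)
        ib = _max_intensity(site, index_b)
        m = math.log2((ia + eps) / (ib + eps))
        a = 0.5 * math.log2((ia + eps) * (ib + eps))
        call = "up_a" if m >= m_min else ("up_b" if m <= -m_min else "common")
        near = [
            (abs(t - site.midpoint), gid)
            for gid, chrom, t in tss_by_gene
            if chrom == site.chrom and abs(t - site.midpoint) <= flank + len(site) // 2
        ]
        nearest = min(near)[1] if near else None
        out.append(DifferentialBindingSite(site, ia, ib, m, a, call, nearest))
    return out


def binding_breadth(
    sites: Sequence[GenomicInterval],
    panel: Mapping[str, Sequence[Peak]],
) -> list[int]:
    """Number of panel cells whose peak set overlaps each site."""
    if len(panel) < 2:
        raise ValueError("panel must contain >= 2 cells")
    indexes = [
        GenomicIndex((p.region, True) for p in peaks) for _, peaks in sorted(panel.items())
    ]
    return [sum(1 for ix in indexes if ix.any_overlap(s)) for s in sites]


def breadth_ks(
    breadth_a: Sequence[int], breadth_b: Sequence[int]
) -> tuple[float, float]:
    """KS comparison of two site groups' binding-breadth distributions."""
    return ks_two_sample(breadth_a, breadth_b)


def methylation_in_regions(
    cpgs: Sequence[CpGRecord],
    regions: Sequence[GenomicInterval],
    level_kind: str = "peak_500bp",
    min_cov: int = 5,
    min_cpgs: int = 1,
) -> list[RegionMethylation]:
    """Coverage-weighted mean beta per region over sufficiently covered CpGs.

    Regions with fewer than ``min_cpgs`` CpGs at coverage >= ``min_cov``
    are reported with beta NA (nan).  Output is independent of CpG input
    order.
    """
    index = GenomicIndex()
    for c in cpgs:
        if c.count_total >= min_cov:
            index.add(GenomicInterval(c.chrom, c.pos, c.pos + 1), c)
    out = []
    for region in regions:
        hits = sorted(index.query(region), key=lambda c: (c.chrom, c.pos))
        if len(hits) < min_cpgs:
            out.append(RegionMethylation(region, level_kind, len(hits), float("nan")))
            continue
        meth = sum(c.count_meth for c in hits)
        total = sum(c.count_total for c in hits)
        out.append(RegionMethylation(region, level_kind, len(hits), meth / total))
    return out


def compare_region_methylation(
    group_a: Sequence[RegionMethylation],
    group_b: Sequence[RegionMethylation],
) -> dict:
    """Rank-sum comparison of two groups' region methylation levels."""
    va = [r.beta_mean for r in group_a if not math.isnan(r.beta_mean)]
    vb = [r.beta_mean for r in group_b if not math.isnan(r.beta_mean)]
    if len(va) < 2 or len(vb) < 2:
        log.warning("insufficient non-NA methylation values for comparison")
        return {"median_a": None, "median_b": None, "p_value": None}
    _, p = wilcoxon_rank_sum(va, vb)
    return {
        "median_a": float(np.median(va)),
        "median_b": float(np.median(vb)),
        "p_value": p,
    }


def call_dmc(
    cpgs_a: Sequence[CpGRecord],
    cpgs_b: Sequence[CpGRecord],
    min_cov: int = 5,
    delta_min: float = 0.25,
    q_max: float = 0.05,
) -> list[DMC]:
    """Differentially methylated cytosines between two states.

    Positions are matched by (chrom, pos); at each shared position with
    both coverages >= ``min_cov`` a Fisher exact test on
    [[meth_a, unmeth_a], [meth_b, unmeth_b]] is BH-corrected across all
    tested positions; a DMC requires q <= q_max and |beta_a - beta_b| >=
    delta_min.
    """
    a_by_pos = {(c.chrom, c.pos): c for c in cpgs_a if c.count_total >= min_cov}
    tested = []
    for cb in cpgs_b:
        if cb.count_total < min_cov:
            continue
        ca = a_by_pos.get((cb.chrom, cb.pos))
        if ca is None:
            continue
        p = fisher_exact_2x2(
            ca.count_meth,
            ca.count_total - ca.count_meth,
            cb.count_meth,
            cb.count_total - cb.count_meth,
        )
        tested.append((ca, cb, p))
    if not tested:
        log.warning("no shared covered positions between the two states")
        return []
    tested.sort(key=lambda t: (t[0].chrom, t[0].pos))
    qvals = benjamini_hochberg([t[2] for t in tested])
    out = []
    for (ca, cb, p), q in zip(tested, qvals):
        delta = ca.beta - cb.beta
        if q <= q_max and abs(delta) >= delta_min:
            out.append(DMC(ca.chrom, ca.pos, ca.beta, cb.beta, delta, p, float(q)))
    return out
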