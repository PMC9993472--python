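"""Interaction domains, CTCF anchor genes, and A/B compartments.

A domain (RAID for RNAPII, CCD for CTCF) is a connected component of the
graph whose nodes are loops and whose edges join loops having any pair of
anchors within ``merge_gap`` bp of each other (overlap when 0).  Gene
membership is decided by the TSS falling in the domain span; a domain is SG
(single-gene) with exactly one member TSS and MG with two or more.

Compartments are the sign of the first principal component of the
correlation matrix of the observed/expected contact matrix, with the A
label oriented to the gene-dense class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import tss_window
from .types import GeneModel, GenomicInterval, Loop

log = logging.getLogger(__name__)

_FACTOR_DOMAIN = {"RNAPII": "RAID", "CTCF": "CCD"}


@dataclass
class InteractionDomain:
    domain_id: str
    factor: str
    span: GenomicInterval
    member_loops: list[int]  # indices into the input loop list
    gene_ids: list[str] = field(default_factory=list)

    @property
    def kind(self) -> str:
        return _FACTOR_DOMAIN[self.factor]

    @property
    def gene_class(self) -> str:
        if len(self.gene_ids) >= 2:
            return "MG"
        if len(self.gene_ids) == 1:
            return "SG"
        return "none"


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_loops_into_domains(
    loops: Sequence[Loop], merge_gap: int = 0
) -> list[InteractionDomain]:
    """Partition single-factor loops into anchor-connected domains.

    Uses a sorted sweep over anchors: anchors whose gap is <= merge_gap
    chain into clusters, and loops sharing an anchor cluster are unioned.
    This equals the all-pairs anchor-proximity graph by transitivity.
    Domain ids are deterministic (ordered by span, then id).
    """
    if not loops:
        return []
    factors = {lp.factor for lp in loops}
    if len(factors) > 1:
        raise ValueError(f"loops must be of a single factor (got {sorted(factors)})")
    factor = factors.pop()

    uf = _UnionFind(len(loops))
    anchors = []
    for i, lp in enumerate(loops):
        anchors.append((lp.chrom, lp.anchor_a.start, lp.anchor_a.end, i))
        anchors.append((lp.chrom, lp.anchor_b.start, lp.anchor_b.end, i))
    anchors.sort()
    cur_chrom = None
    cur_end = -1
    cur_rep = -1
    for chrom, start, end, loop_idx in anchors:
        if chrom == cur_chrom and start <= cur_end + merge_gap:
            uf.union(cur_rep, loop_idx)
            cur_end = max(cur_end, end)
        else:
            cur_chrom, cur_end, cur_rep = chrom, end, loop_idx

    members: dict[int, list[int]] = {}
    for i in range(len(loops)):
        members.setdefault(uf.find(i), []).append(i)

    domains = []
    for idxs in members.values():
        chrom = loops[idxs[0]].chrom
        start = min(loops[i].anchor_a.start for i in idxs)
        end = max(loops[i].anchor_b.end for i in idxs)
        domains.append((GenomicInterval(chrom, start, end), sorted(idxs)))
    domains.sort(key=lambda d: (d[0].chrom, d[0].start, d[0].end))
    out = [
        InteractionDomain(f"{_FACTOR_DOMAIN[factor]}_{i:04d}", factor, span, idxs)
        for i, (span, idxs) in enumerate(domains)
    ]
    assert sum(len(d.member_loops) for d in out) == len(loops)
    return out


def assign_genes_to_domains(
    domains: Sequence[InteractionDomain],
    genes: Sequence[GeneModel],
    subset: Sequence[str] | None = None,
) -> tuple[dict[str, str], float]:
    """Assign genes to domains by TSS containment.

    Fills each domain's ``gene_ids`` in place and returns the per-gene
    mapping (gene_id -> domain_id, or "outside") plus the fraction of the
    designated gene subset (all genes when None) located inside a domain.
    """
    for d in domains:
        d.gene_ids = []
    mapping: dict[str, str] = {}
    # domains of one factor never overlap after clustering at merge_gap=0,
    # so first hit wins; kept simple at desk scale
    for g in genes:
        mapping[g.gene_id] = "outside"
        for d in domains:
            if d.span.chrom == g.chrom and d.span.start <= g.tss < d.span.end:
                mapping[g.gene_id] = d.domain_id
                d.gene_ids.append(g.gene_id)
                break
    focus = list(subset) if subset is not None else [g.gene_id for g in genes]
    if not focus:
        return mapping, 0.0
    inside = sum(1 for gid in focus if mapping.get(gid, "outside") != "outside")
    return mapping, inside / len(focus)


def genes_with_anchor_at_tss(
    loops: Sequence[Loop],
    genes: Sequence[GeneModel],
    flank: int = 2000,
) -> dict[str, int]:
    """Genes with >= 1 loop anchor at the promoter, with anchor counts.

    Each anchor of each loop is counted once; a gene appears once however
    many anchors hit it.
    """
    from .intervals import GenomicIndex

    index = GenomicIndex()
    for lp in loops:
        index.add(lp.anchor_a, 1)
        index.add(lp.anchor_b, 1)
    counts: dict[str, int] = {}
    for g in genes:
        n = len(index.query(tss_window(g, flank)))
        if n:
            counts[g.gene_id] = n
    return counts


@dataclass
class CompartmentTrack:
    binsize: int
    labels: list[str]  # per-bin "A" | "B" | "NA"
    eigenvalue_fraction: float


def call_compartments(
    matrix: np.ndarray,
    binsize: int,
    gene_density: Sequence[float],
) -> CompartmentTrack:
    """A/B compartment labels from a binned contact matrix.

    Pipeline: distance-normalize (observed/expected by diagonal mean),
    correlate bins, take the first principal component, and label bins by
    its sign.  Orientation: the class with the higher mean gene density is
    A.  Bins with a zero contact marginal are NA.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("contact matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("contact matrix must be symmetric")
    if np.any(m < 0):
        raise ValueError("contact matrix must be non-negative")
    if not np.any(m):
        raise ValueError("all-zero contact matrix")
    n = m.shape[0]
    gene_density = np.asarray(gene_density, dtype=float)
    if gene_density.shape != (n,):
        raise ValueError("gene_density must have one entry per bin")

    marginal = m.sum(axis=0)
    good = marginal > 0
    labels = ["NA"] * n
    sub = m[np.ix_(good, good)]
    k = sub.shape[0]
    # observed / expected by diagonal
    oe = np.ones_like(sub)
    for d in range(k):
        diag = np.diagonal(sub, offset=d)
        mu = diag.mean()
        if mu > 0:
            idx = np.arange(k - d)
            oe[idx, idx + d] = diag / mu
            oe[idx + d, idx] = diag / mu
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(oe)
    if np.any(~np.isfinite(corr)):
        log.warning("degenerate contact matrix: constant O/E rows; labels NA")
        return CompartmentTrack(binsize, labels, 0.0)
    corr_c = corr - corr.mean(axis=0, keepdims=True)
    cov = corr_c.T @ corr_c
    evals, evecs = np.linalg.eigh(cov)
    ev1 = evecs[:, -1]
    total = float(evals.sum())
    frac = float(evals[-1] / total) if total > 0 else 0.0
    if frac < 1e-9 or np.allclose(ev1, ev1[0]):
        log.warning("no compartment structure (eigenvalue fraction ~ 0)")
        return CompartmentTrack(binsize, labels, frac)
    signs = np.where(ev1 >= 0, "A", "B")
    dens = gene_density[good]
    mean_a = dens[signs == "A"].mean() if np.any(signs == "A") else -np.inf
    mean_b = dens[signs == "B"].mean() if np.any(signs == "B") else -np.inf
    if mean_b > mean_a:  # orient: gene-dense class is A
        signs = np.where(signs == "A", "B", "A")
    for i, gi in enumerate(np.flatnonzero(good)):
        labels[gi] = str(signs[i])
    return CompartmentTrack(binsize, labels, frac)


def compartment_switch(
    track_a: CompartmentTrack,
    track_b: CompartmentTrack,
    genes: Sequence[GeneModel],
    subset: Sequence[str] | None = None,
) -> tuple[dict[str, str], float]:
    """Per-gene compartment switch class between two tracks.

    A gene's bin is ``tss // binsize``; classes are "B->A", "A->B",
    "stable", or "NA" (either label NA or bin out of range).  Also returns
    the fraction of the designated subset with a B->A switch.
    """
    if track_a.binsize != track_b.binsize:
        raise ValueError("binsize mismatch between tracks")
    if len(track_a.labels) != len(track_b.labels):
        raise ValueError("bin count mismatch between tracks")
    out: dict[str, str] = {}
    for g in genes:
        b = g.tss // track_a.binsize
        if b >= len(track_a.labels):
            out[g.gene_id] = "NA"
            continue
        la, lb = track_a.labels[b], track_b.labels[b]
        if "NA" in (la, lb):
            out[g.gene_id] = "NA"
        elif la == lb:
            out[g.gene_id] = "stable"
        else:
            out[g.gene_id] = f"{la}->{lb}"
    focus = list(subset) if subset is not None else [g.gene_id for g in genes]
    if not focus:
        return out, 0.0
    ba = sum(1 for gid in focus if out.get(gid) == "B->A")
    return out, ba / len(focus)


def contact_matrix_from_loops(
    loops: Sequence[Loop], chrom: str, chrom_length: int, binsize: int
) -> np.ndarray:
    """Synthesize a symmetric binned contact matrix from loops.

    Each loop adds its PET count to the cell of its two anchor bins
    (midpoint binning); desk-scale stand-in for a Hi-C input.
    """
    n = int(np.ceil(chrom_length / binsize))
    m = np.zeros((n, n))
    for lp in loops:
        if lp.chrom != chrom:
            continue
        i = lp.anchor_a.midpoint // binsize
        j = lp.anchor_b.midpoint // binsize
        if i < n and j < n:
            m[i, j] += lp.pet_count
            if i != j:
                m[j, i] += lp.pet_count
    return m
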