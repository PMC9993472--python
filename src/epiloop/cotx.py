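"""Co-transcription of promoter-promoter connected gene pairs.

Gene pairs joined by P-P (optionally Ep-P / Ep-Ep) loops are correlated
across an expression panel (Pearson), and the observed mean correlation is
compared against a degree-preserving rewired null: each permutation
randomly rematches the multiset of genes appearing in the pairs, rejecting
self-pairs and observed pairs, so every gene keeps its pairing
multiplicity.  The empirical p-value uses the add-one estimator
``(1 + #{null mean r >= observed}) / (n_perm + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .elements import EPNetwork
from .types import ExpressionTable

log = logging.getLogger(__name__)

_PP_TYPES = {"P-P", "Ep-P", "Ep-Ep"}


@dataclass(frozen=True)
class PairCorrelation:
    gene_a: str
    gene_b: str
    r: float
    n_samples: int


def extract_pp_pairs(
    network: EPNetwork, include_ep: bool = True
) -> list[tuple[str, str]]:
    """Deduplicated unordered gene pairs joined by promoter-promoter edges."""
    types = _PP_TYPES if include_ep else {"P-P"}
    pairs = set()
    for edge in network.edges:
        if edge.edge_type not in types:
            continue
        if len(edge.gene_ids) != 2 or edge.gene_ids[0] == edge.gene_ids[1]:
            continue
        pairs.add(tuple(sorted(edge.gene_ids)))
    return sorted(pairs)


def _correlation_lookup(
    genes: Sequence[str], panel: ExpressionTable
) -> tuple[dict[str, int], np.ndarray, np.ndarray]:
    """Gene index, centered/normalized profile matrix, and validity mask."""
    missing = [g for g in genes if g not in panel.frame.index]
    if missing:
        raise KeyError(f"genes absent from panel: {missing[:5]}")
    mat = panel.frame.loc[list(genes)].to_numpy(dtype=float)
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    valid = norms > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = centered / norms[:, None]
    unit[~valid] = 0.0
    return {g: i for i, g in enumerate(genes)}, unit, valid


def pair_pearson(
    pairs: Sequence[tuple[str, str]],
    panel: ExpressionTable,
    r_min: float = 0.25,
) -> tuple[list[PairCorrelation], float]:
    """Pearson r per gene pair across the panel, plus fraction with r > r_min.

    Pairs involving a zero-variance gene have undefined r and are excluded
    from the fraction denominator (logged).
    """
    n_samples = len(panel.samples)
    if n_samples < 3:
        raise ValueError("panel must have >= 3 samples")
    genes = sorted({g for pair in pairs for g in pair})
    idx, unit, valid = _correlation_lookup(genes, panel)
    out: list[PairCorrelation] = []
    defined = 0
    above = 0
    for ga, gb in pairs:
        ia, ib = idx[ga], idx[gb]
        if not (valid[ia] and valid[ib]):
            log.warning("pair (%s, %s): zero-variance profile, r undefined", ga, gb)
            out.append(PairCorrelation(ga, gb, float("nan"), n_samples))
            continue
        r = float(np.clip(np.dot(unit[ia], unit[ib]), -1.0, 1.0))
        out.append(PairCorrelation(ga, gb, r, n_samples))
        defined += 1
        if r > r_min:
            above += 1
    fraction = above / defined if defined else float("nan")
    return out, fraction


def _rematch(
    slots: list[str],
    observed: set[tuple[str, str]],
    rng: np.random.Generator,
    max_tries: int = 200,
) -> list[tuple[str, str]] | None:
    for _ in range(max_tries):
        perm = list(rng.permutation(slots))
        cand = [tuple(sorted((perm[i], perm[i + 1]))) for i in range(0, len(perm), 2)]
        if any(a == b for a, b in cand):
            continue
        if any(p in observed for p in cand):
            continue
        return cand
    return None


def rewired_null(
    pairs: Sequence[tuple[str, str]],
    panel: ExpressionTable,
    n_perm: int = 1000,
    seed: int = 0,
    degree_preserving: bool = True,
) -> dict:
    """Empirical p for the observed mean pair correlation vs a rewired null.

    Each permutation rematches the multiset of gene slots into new pairs
    (degree preserved), rejecting self-pairs and observed pairs; with
    ``degree_preserving=False`` partners are drawn uniformly from the
    panel's gene universe instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(pairs) < 2:
        raise ValueError("need >= 2 pairs for a rewired null")
    slots = [g for pair in pairs for g in pair]
    if len(set(slots)) < 2:
        raise ValueError("rematching impossible: fewer than 2 distinct genes")

    universe = sorted(set(slots)) if degree_preserving else sorted(panel.frame.index)
    idx, unit, valid = _correlation_lookup(universe, panel)

    def mean_r(pair_list: Sequence[tuple[str, str]]) -> float:
        rs = []
        for ga, gb in pair_list:
            ia, ib = idx[ga], idx[gb]
            if valid[ia] and valid[ib]:
                rs.append(float(np.dot(unit[ia], unit[ib])))
        return float(np.mean(rs)) if rs else float("nan")

    observed_set = {tuple(sorted(p)) for p in pairs}
    obs = mean_r(pairs)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        if degree_preserving:
            cand = _rematch(slots, observed_set, rng)
            if cand is None:
                raise RuntimeError("degree-preserving rematching failed repeatedly")
        else:
            cand = []
            pool = universe
            for _ in range(len(pairs)):
                ga, gb = rng.choice(pool, size=2, replace=False)
                cand.append((str(ga), str(gb)))
        # every permutation preserves pairing multiplicity by construction
        if degree_preserving:
            assert sorted(g for p in cand for g in p) == sorted(slots)
        null[b] = mean_r(cand)
    p = (1 + int(np.sum(null >= obs - 1e-12))) / (n_perm + 1)
    return {
        "observed_mean_r": obs,
        "null_mean_r": null,
        "empirical_p": p,
        "n_perm": n_perm,
    }
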