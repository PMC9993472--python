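"""Statistical kernels and the two enrichment applications.

Kernels: Wilcoxon rank-sum (exact permutation enumeration for small pooled
n, tie- and continuity-corrected normal approximation otherwise), pooled
two-proportion z, log-space hypergeometric upper tail, two-sample
Kolmogorov-Smirnov, Fisher exact 2x2, and both-strand PWM scanning.

Applications: TF occupancy ranking between two element sets (two-proportion
z per TF) and LD expansion of GWAS lead SNPs followed by element-level
hypergeometric enrichment.

No multiple-testing correction is applied inside kernels; the reporting
layer applies Benjamini-Hochberg when many simultaneous tests are emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicIndex
from .types import GenomicInterval, Peak, SNPRecord

log = logging.getLogger(__name__)

EXACT_RANKSUM_MAX_N = 12  # pooled-size crossover from enumeration to z


# ---------------------------------------------------------------------------
# Kernels


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U for ``x`` vs ``y`` with a two-sided p-value.

    Exact permutation enumeration over all C(n+m, n) labelings when the
    pooled size is <= 12 (valid under ties); otherwise the normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n]) - n * (n + 1) / 2.0)
    mean_u = n * m / 2.0

    if n + m <= EXACT_RANKSUM_MAX_N:
        dev_obs = abs(u_obs - mean_u)
        count = 0
        total = 0
        all_idx = range(n + m)
        for subset in combinations(all_idx, n):
            u = float(np.sum(ranks[list(subset)]) - n * (n + 1) / 2.0)
            if abs(u - mean_u) >= dev_obs - 1e-9:
                count += 1
            total += 1
        return u_obs, count / total

    # tie-corrected variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    nm = n + m
    var_u = n * m / 12.0 * ((nm + 1) - tie_term / (nm * (nm - 1)))
    if var_u <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mean_u) - 0.5) / np.sqrt(var_u)
    z = max(z, 0.0)
    return u_obs, float(min(1.0, 2.0 * sps.norm.sf(z)))


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z-test, two-sided."""
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        log.debug("two_proportion_z degenerate pooled proportion %s", pooled)
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), summed in log space."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"impossible hypergeometric parameters N={N} K={K} n={n} k={k}")
    hi = min(n, K)
    if k > hi:
        return 0.0
    if k == 0:
        return 1.0
    ks = np.arange(k, hi + 1)
    logp = sps.hypergeom.logpmf(ks, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic D with the asymptotic Kolmogorov p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table entries must be non-negative")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (monotone step-up)."""
    if len(pvalues) == 0:
        return np.array([])
    return multipletests(pvalues, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# PWM scanning

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class MotifHit:
    position: int  # forward-strand start of the hit window
    strand: str
    score: float


def _scan_strand(sequence: str, pwm: np.ndarray) -> np.ndarray:
    w = pwm.shape[0]
    scores = np.zeros(len(sequence) - w + 1)
    col_idx = np.array([_BASE_INDEX.get(b, -1) for b in sequence])
    for offset in range(w):
        bases = col_idx[offset : offset + len(scores)]
        valid = bases >= 0
        scores[valid] += pwm[offset, bases[valid]]
        # non-ACGT bases contribute 0 (logged by caller)
    return scores


def pwm_scan(
    sequence: str, pwm: np.ndarray, threshold: float
) -> list[MotifHit]:
    """Scan both strands with a (width x 4) log-odds matrix over ACGT.

    Reverse-strand hits are reported at their forward-coordinate start.
    Non-ACGT bases contribute a score of 0 at their position.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("pwm must have shape (width, 4) over ACGT")
    w = pwm.shape[0]
    sequence = sequence.upper()
    if w > len(sequence):
        raise ValueError("pwm wider than sequence")
    if any(b not in _BASE_INDEX for b in set(sequence)):
        log.warning("sequence contains non-ACGT bases; scored as 0 contribution")

    hits: list[MotifHit] = []
    fwd = _scan_strand(sequence, pwm)
    for pos in np.flatnonzero(fwd >= threshold):
        hits.append(MotifHit(int(pos), "+", float(fwd[pos])))
    rc = sequence.translate(_COMPLEMENT)[::-1]
    rev = _scan_strand(rc, pwm)
    for pos in np.flatnonzero(rev >= threshold):
        fwd_pos = len(sequence) - w - int(pos)
        hits.append(MotifHit(fwd_pos, "-", float(rev[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Applications


@dataclass(frozen=True)
class EnrichmentResult:
    set_label: str
    k: int  # overlapping members of the target set
    n: int  # target set size
    K: int  # universe positives
    N: int  # universe size
    p_value: float


@dataclass(frozen=True)
class TFOccupancyRow:
    tf_name: str
    frac_a: float
    frac_b: float
    z: float
    p_value: float
    note: str = ""


def _fraction_overlapped(
    regions: Sequence[GenomicInterval], peaks: Sequence[Peak]
) -> tuple[int, float]:
    index = GenomicIndex((p.region, True) for p in peaks)
    hit = sum(1 for r in regions if index.any_overlap(r))
    return hit, hit / len(regions)


def tf_occupancy_ranking(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    tf_peaksets: Mapping[str, Sequence[Peak]],
) -> list[TFOccupancyRow]:
    """Rank TFs by occupancy difference between two element sets.

    For each TF the fraction of each set overlapped by >= 1 peak is
    computed; rows are ranked by ``frac_a - frac_b`` descending with a
    two-proportion z attached.
    """
    if not set_a or not set_b:
        raise ValueError("both element sets must be non-empty")
    rows: list[TFOccupancyRow] = []
    for tf_name in sorted(tf_peaksets):
        peaks = tf_peaksets[tf_name]
        if len(peaks) == 0:
            rows.append(TFOccupancyRow(tf_name, 0.0, 0.0, 0.0, 1.0, "empty peakset"))
            continue
        ka, fa = _fraction_overlapped(set_a, peaks)
        kb, fb = _fraction_overlapped(set_b, peaks)
        z, p = two_proportion_z(ka, len(set_a), kb, len(set_b))
        rows.append(TFOccupancyRow(tf_name, fa, fb, z, p))
    rows.sort(key=lambda r: (-(r.frac_a - r.frac_b), r.tf_name))
    return rows


def expand_ld(
    leads: Sequence[SNPRecord],
    ld_pairs: Sequence[tuple[str, SNPRecord, float]],
    r2_min: float = 0.8,
    strict: bool = True,
) -> list[SNPRecord]:
    """Expand lead SNPs with LD satellites at r^2 >= ``r2_min``.

    ``ld_pairs`` rows are (lead_rsid, satellite record, r2); satellites
    inherit the trait class of their lead.
    """
    by_rsid = {s.rsid: s for s in leads}
    out: list[SNPRecord] = list(leads)
    seen = set(by_rsid)
    for lead_rsid, satellite, r2 in ld_pairs:
        lead = by_rsid.get(lead_rsid)
        if lead is None:
            if strict:
                raise KeyError(f"LD pair cites unknown lead SNP {lead_rsid!r}")
            continue
        if r2 < r2_min or satellite.rsid in seen:
            continue
        out.append(
            SNPRecord(
                rsid=satellite.rsid,
                chrom=satellite.chrom,
                pos=satellite.pos,
                trait_class=lead.trait_class,
                lead_rsid=lead_rsid,
                r2=r2,
            )
        )
        seen.add(satellite.rsid)
    return out


def snp_element_enrichment(
    snps: Sequence[SNPRecord],
    target_elements: Sequence[GenomicInterval],
    universe_elements: Sequence[GenomicInterval],
    set_label: str = "target",
    background_snps: Sequence[SNPRecord] | None = None,
) -> EnrichmentResult:
    """Hypergeometric enrichment of SNP-containing elements in a target set.

    Default (element universe): N = |universe|, K = universe elements with
    >= 1 SNP, n = |target|, k = target elements with >= 1 SNP; p is the
    upper hypergeometric tail.  Supplying ``background_snps`` switches to
    the SNP-universe mode: N = |background|, K = background SNPs inside a
    target element, n = |snps|, k = trait SNPs inside a target element
    (the trait set must be drawn from the background).
    """
    universe_set = set(universe_elements)
    if any(t not in universe_set for t in target_elements):
        raise ValueError("target elements must be a subset of the universe")
    if background_snps is not None:
        target_index = GenomicIndex((e, True) for e in target_elements)

        def in_target(s: SNPRecord) -> bool:
            return target_index.any_overlap(GenomicInterval(s.chrom, s.pos, s.pos + 1))

        N = len(background_snps)
        K = sum(1 for s in background_snps if in_target(s))
        n = len(snps)
        k = sum(1 for s in snps if in_target(s))
        return EnrichmentResult(set_label, k, n, K, N, hypergeometric_tail(N, K, n, k))
    snp_index = GenomicIndex(
        (GenomicInterval(s.chrom, s.pos, s.pos + 1), s.rsid) for s in snps
    )
    N = len(universe_set)
    K = sum(1 for e in universe_set if snp_index.any_overlap(e))
    n = len(target_elements)
    k = sum(1 for e in target_elements if snp_index.any_overlap(e))
    return EnrichmentResult(set_label, k, n, K, N, hypergeometric_tail(N, K, n, k))
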