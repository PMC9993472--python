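"""Statistical kernels against enumeration oracles and closed forms."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from epiloop import stats
from epiloop.types import GenomicInterval, Peak, SNPRecord


def ranksum_enumeration_p(x, y, two_sided=True):
    """Independent oracle: enumerate all labelings of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    mean_u = n * len(y) / 2.0
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    count = total = 0
    for subset in combinations(range(len(pooled)), n):
        u = ranks[list(subset)].sum() - n * (n + 1) / 2.0
        if two_sided:
            hit = abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9
        else:
            hit = u >= u_obs - 1e-9
        count += hit
        total += 1
    return count / total


class TestWilcoxonRankSum:
    def test_fully_separated_small_samples(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        u, p = stats.wilcoxon_rank_sum(x, y)
        assert u == 0.0
        # one-sided exact tail of the most extreme labeling is 1/20
        assert ranksum_enumeration_p(y, x, two_sided=False) == pytest.approx(1 / 20)
        assert p == pytest.approx(2 / 20)

    def test_identical_multisets(self):
        x = [1.0, 2.0, 2.0, 5.0]
        u, p = stats.wilcoxon_rank_sum(x, list(x))
        assert u == len(x) ** 2 / 2
        assert p == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(1, 7))
            m = int(rng.integers(1, 13 - n))
            x = rng.integers(0, 5, n).astype(float)  # ties likely
            y = rng.integers(0, 5, m).astype(float)
            _, p = stats.wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(ranksum_enumeration_p(x, y), abs=1e-12)

    def test_exact_matches_scipy_when_tie_free(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.permutation(12)[:5].astype(float)
            y = rng.permutation(np.arange(20, 32))[:6].astype(float)
            _, p = stats.wilcoxon_rank_sum(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_sample_approximation_close_to_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        _, p = stats.wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestTwoProportionZ:
    def test_equal_proportions(self):
        assert stats.two_proportion_z(5, 10, 5, 10) == (0.0, 1.0)

    def test_direct_formula(self):
        z, _ = stats.two_proportion_z(9, 10, 1, 10)
        assert z == pytest.approx(0.8 / np.sqrt(0.5 * 0.5 * 0.2), rel=1e-4)

    def test_degenerate_pooled(self):
        assert stats.two_proportion_z(0, 10, 0, 10) == (0.0, 1.0)
        assert stats.two_proportion_z(10, 10, 10, 10) == (0.0, 1.0)

    def test_z_squared_is_chi2_without_continuity(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            k1, k2 = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            z, _ = stats.two_proportion_z(k1, 10, k2, 10)
            table = [[k1, 10 - k1], [k2, 10 - k2]]
            chi2 = sps.chi2_contingency(table, correction=False)[0]
            assert z**2 == pytest.approx(chi2, rel=1e-9)


def hypergeom_enumeration(N, K, n, k):
    """Count n-subsets of an N-universe with >= k of the K positives."""
    hits = 0
    total = 0
    for subset in combinations(range(N), n):
        total += 1
        if sum(1 for i in subset if i < K) >= k:
            hits += 1
    return hits / total


class TestHypergeometricTail:
    def test_known_value(self):
        assert stats.hypergeometric_tail(10, 4, 5, 3) == pytest.approx(66 / 252)

    def test_certain_event(self):
        assert stats.hypergeometric_tail(10, 4, 5, 0) == 1.0

    def test_small_enumeration(self):
        assert stats.hypergeometric_tail(4, 2, 2, 2) == pytest.approx(1 / 6)

    def test_matches_enumeration_on_small_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            N = int(rng.integers(2, 11))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, n + 1))
            assert stats.hypergeometric_tail(N, K, n, k) == pytest.approx(
                hypergeom_enumeration(N, K, n, k), abs=1e-12
            )

    def test_monotone_non_increasing_in_k(self):
        tails = [stats.hypergeometric_tail(20, 8, 10, k) for k in range(9)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))

    def test_impossible_parameters(self):
        with pytest.raises(ValueError):
            stats.hypergeometric_tail(10, 12, 5, 1)


class TestFisherExact:
    def test_no_association(self):
        assert stats.fisher_exact_2x2(1, 1, 1, 1) == 1.0

    def test_perfect_separation(self):
        assert stats.fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_one_sided_extreme_agrees_with_hypergeometric(self):
        # for the most extreme table the two-sided Fisher p equals the sum of
        # both one-sided hypergeometric tails
        p = stats.fisher_exact_2x2(4, 0, 0, 4)
        tail = stats.hypergeometric_tail(8, 4, 4, 4)
        assert p == pytest.approx(2 * tail)


class TestKS:
    def test_identical(self):
        d, p = stats.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_supports(self):
        d, _ = stats.ks_two_sample([1.0, 2.0], [3.0, 4.0])
        assert d == 1.0

    def test_interleaved(self):
        d, _ = stats.ks_two_sample([1.0, 3.0], [2.0, 4.0])
        assert d == 0.5


class TestPWMScan:
    # strongly informative 4-mer PWM, non-palindromic consensus AACG
    pwm = np.log2(
        np.array(
            [
                [0.97 if "ACGT"[j] == base else 0.01 for j in range(4)]
                for base in "AACG"
            ]
        )
        / 0.25
    )

    def test_consensus_single_hit(self):
        max_score = float(self.pwm.max(axis=1).sum())
        hits = stats.pwm_scan("AACG", self.pwm, max_score)
        assert len(hits) == 1
        assert (hits[0].position, hits[0].strand) == (0, "+")

    def test_threshold_above_max_is_empty(self):
        max_score = float(self.pwm.max(axis=1).sum())
        assert stats.pwm_scan("ACGTACGT", self.pwm, max_score + 1) == []

    def test_reverse_strand_reported_in_forward_coordinates(self):
        # consensus AACG; its reverse complement CGTT sits at position 2
        hits = stats.pwm_scan("TTCGTTTT", self.pwm, float(self.pwm.max(axis=1).sum()))
        assert [(h.position, h.strand) for h in hits] == [(2, "-")]

    def test_matches_brute_force_rescan(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        w = self.pwm.shape[0]
        threshold = 4.0
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        expected = []
        for pos in range(len(seq) - w + 1):
            fwd = sum(self.pwm[i, idx[seq[pos + i]]] for i in range(w))
            if fwd >= threshold:
                expected.append((pos, "+"))
            window = seq[pos : pos + w]
            rc = "".join(comp[b] for b in reversed(window))
            rev = sum(self.pwm[i, idx[rc[i]]] for i in range(w))
            if rev >= threshold:
                expected.append((pos, "-"))
        got = [(h.position, h.strand) for h in stats.pwm_scan(seq, self.pwm, threshold)]
        assert sorted(got) == sorted(expected)


class TestLDAndEnrichment:
    leads = [SNPRecord("rs1", "chr1", 1000, "cancer_related")]

    def make_pairs(self):
        return [
            ("rs1", SNPRecord("rs2", "chr1", 1500, "other"), 0.9),
            ("rs1", SNPRecord("rs3", "chr1", 2500, "other"), 0.5),
        ]

    def test_threshold(self):
        out = stats.expand_ld(self.leads, self.make_pairs(), r2_min=0.8)
        assert {s.rsid for s in out} == {"rs1", "rs2"}
        assert all(s.trait_class == "cancer_related" for s in out)

    def test_r2_zero_includes_all(self):
        out = stats.expand_ld(self.leads, self.make_pairs(), r2_min=0.0)
        assert {s.rsid for s in out} == {"rs1", "rs2", "rs3"}

    def test_empty_pairs(self):
        assert stats.expand_ld(self.leads, [], r2_min=0.8) == self.leads

    def test_monotone_in_r2_min(self):
        prev = None
        for r2_min in (0.0, 0.4, 0.8, 1.0):
            cur = {s.rsid for s in stats.expand_ld(self.leads, self.make_pairs(), r2_min)}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_unknown_lead_strict(self):
        pair = [("rsX", SNPRecord("rs9", "chr1", 10, "other"), 0.95)]
        with pytest.raises(KeyError):
            stats.expand_ld(self.leads, pair, strict=True)
        assert stats.expand_ld(self.leads, pair, strict=False) == self.leads

    def test_element_enrichment_known_value(self):
        universe = [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(10)]
        target = universe[:5]
        # SNPs hit universe elements 0,1,2 (in target) and 8 (outside)
        snps = [
            SNPRecord(f"rs{i}", "chr1", e.start + 10, "cancer_related")
            for i, e in enumerate([universe[0], universe[1], universe[2], universe[8]])
        ]
        res = stats.snp_element_enrichment(snps, target, universe)
        assert (res.N, res.K, res.n, res.k) == (10, 4, 5, 3)
        assert res.p_value == pytest.approx(66 / 252)

    def test_no_snps(self):
        universe = [GenomicInterval("chr1", 0, 50)]
        res = stats.snp_element_enrichment([], universe, universe)
        assert res.k == 0
        assert res.p_value == 1.0

    def test_target_must_be_subset(self):
        universe = [GenomicInterval("chr1", 0, 50)]
        stranger = [GenomicInterval("chr2", 0, 50)]
        with pytest.raises(ValueError):
            stats.snp_element_enrichment([], stranger, universe)


class TestTFOccupancyRanking:
    def regions(self, n, offset=0):
        return [
            GenomicInterval("chr1", offset + i * 1000, offset + i * 1000 + 200)
            for i in range(n)
        ]

    def peaks_on(self, regions):
        return [Peak(r, "TF:X", 1.0) for r in regions]

    def test_ordering(self):
        set_a, set_b = self.regions(4), self.regions(4, offset=100_000)
        tfs = {
            "biased": self.peaks_on(set_a[:3] + set_b[:1]),
            "uniform": self.peaks_on(set_a[:2] + set_b[:2]),
        }
        rows = stats.tf_occupancy_ranking(set_a, set_b, tfs)
        assert [r.tf_name for r in rows] == ["biased", "uniform"]
        assert rows[0].frac_a == 0.75 and rows[0].frac_b == 0.25

    def test_identical_sets_give_zero_z(self):
        set_a = self.regions(4)
        tfs = {"X": self.peaks_on(set_a)}
        rows = stats.tf_occupancy_ranking(set_a, set_a, tfs)
        assert rows[0].z == 0.0

    def test_empty_peakset_retained_with_note(self):
        set_a, set_b = self.regions(3), self.regions(3, offset=100_000)
        rows = stats.tf_occupancy_ranking(set_a, set_b, {"empty": []})
        assert rows[0].frac_a == 0.0 and rows[0].note == "empty peakset"
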