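"""Enhancer states, promoter strength, anchor annotation, E-P network."""

from itertools import chain, combinations

import numpy as np
import pytest

from epiloop import elements as el
from epiloop.intervals import SignalTrack
from epiloop.types import GeneModel, GenomicInterval, Loop, Peak


def gene(tss, gid="g", chrom="chr1"):
    return GeneModel(gid, gid, GenomicInterval(chrom, tss, tss + 5000, "+"), "+")


def enhancer(start, end, state="active"):
    return el.RegulatoryElement(
        GenomicInterval("chr1", start, end), "enhancer", state, frozenset({"H3K4me1"})
    )


class TestEnhancerState:
    @pytest.mark.parametrize(
        "marks, expected",
        [
            ({"H3K4me1", "H3K27ac"}, "active"),
            ({"H3K4me1"}, "intermediate"),
            ({"H3K4me1", "H3K27me3"}, "poised"),
            ({"H3K27ac"}, "unclassified"),
            (set(), "unclassified"),
            ({"H3K4me1", "H3K27ac", "H3K27me3"}, "active"),
        ],
    )
    def test_state_rules(self, marks, expected):
        assert el.classify_enhancer_state(marks) == expected

    def test_total_over_all_mark_subsets(self):
        marks = ["H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3"]
        subsets = chain.from_iterable(
            combinations(marks, r) for r in range(len(marks) + 1)
        )
        for sub in subsets:
            state = el.classify_enhancer_state(set(sub))
            assert state in {"active", "intermediate", "poised", "unclassified"}


class TestPromoterStrength:
    def track(self, value):
        return SignalTrack([("chr1", 0, 100_000, value)])

    def test_enhancer_like(self):
        score = el.promoter_strength_score(gene(5000), self.track(2.0), self.track(8.0))
        assert score.log2_ratio == pytest.approx(np.log2(2.1 / 8.1))
        assert score.klass == "enhancer_like"

    def test_strong_mirror(self):
        score = el.promoter_strength_score(gene(5000), self.track(8.0), self.track(2.0))
        assert score.log2_ratio == pytest.approx(np.log2(8.1 / 2.1))
        assert score.klass == "strong"

    def test_tie_is_strong(self):
        score = el.promoter_strength_score(gene(5000), self.track(4.0), self.track(4.0))
        assert score.log2_ratio == 0.0
        assert score.klass == "strong"

    def test_antisymmetric_under_signal_swap(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a, b = rng.uniform(0, 10, 2)
            fwd = el.promoter_strength_score(gene(5000), self.track(a), self.track(b))
            rev = el.promoter_strength_score(gene(5000), self.track(b), self.track(a))
            assert fwd.log2_ratio == pytest.approx(-rev.log2_ratio)


class TestEnhancerUniverse:
    def test_promoter_overlap_and_anchor_requirement(self):
        g = gene(10_000)
        peaks = [
            Peak(GenomicInterval("chr1", 9_500, 10_500), "H3K4me1", 1.0),  # in TSS win
            Peak(GenomicInterval("chr1", 30_000, 31_000), "H3K4me1", 1.0),  # at anchor
            Peak(GenomicInterval("chr1", 60_000, 61_000), "H3K4me1", 1.0),  # orphan
        ]
        loops = [
            Loop.make(
                GenomicInterval("chr1", 9_000, 11_000),
                GenomicInterval("chr1", 30_200, 30_800),
                3,
                "RNAPII",
            )
        ]
        got = el.build_enhancer_elements(peaks, [g], loops)
        assert [e.region.start for e in got] == [30_000]
        # without the anchor requirement the orphan peak is kept too
        loose = el.build_enhancer_elements(
            peaks, [g], loops, require_anchor_overlap=False
        )
        assert [e.region.start for e in loose] == [30_000, 60_000]


class TestAnchorAnnotation:
    def annotator(self, klass="strong"):
        g = gene(10_000)
        strength = el.PromoterStrength("g", 1, 1, 1.0 if klass == "strong" else -1.0, klass)
        return el.AnchorAnnotator([g], {"g": strength}, [enhancer(9_000, 12_000)])

    def test_promoter_precedence_over_enhancer(self):
        ann = self.annotator().annotate(GenomicInterval("chr1", 9_500, 10_500))
        assert ann.label == "P" and ann.gene_id == "g"

    def test_enhancer_like_promoter(self):
        ann = self.annotator("enhancer_like").annotate(
            GenomicInterval("chr1", 9_500, 10_500)
        )
        assert ann.label == "Ep"

    def test_enhancer_only(self):
        annot = el.AnchorAnnotator([gene(100_000)], {}, [enhancer(9_000, 12_000)])
        ann = annot.annotate(GenomicInterval("chr1", 9_500, 10_500))
        assert ann.label == "E"

    def test_nothing(self):
        annot = el.AnchorAnnotator([gene(100_000)], {}, [])
        assert annot.annotate(GenomicInterval("chr1", 0, 100)).label == "none"

    def test_two_tss_windows_take_nearest(self):
        g1, g2 = gene(10_000, "g1"), gene(13_000, "g2")
        annot = el.AnchorAnnotator([g1, g2], {}, [])
        ann = annot.annotate(GenomicInterval("chr1", 11_900, 12_200))
        assert ann.gene_id == "g2"


class TestEPNetwork:
    def setup_method(self):
        self.g1, self.g2 = gene(10_000, "g1"), gene(200_000, "g2")
        self.enh = enhancer(50_000, 52_000)
        strengths = {
            "g1": el.PromoterStrength("g1", 8, 2, 1.9, "strong"),
            "g2": el.PromoterStrength("g2", 8, 2, 1.9, "strong"),
        }
        self.annot = el.AnchorAnnotator(
            [self.g1, self.g2], strengths, [self.enh]
        )

    def loop(self, a0, a1, b0, b1):
        return Loop.make(
            GenomicInterval("chr1", a0, a1), GenomicInterval("chr1", b0, b1), 2, "RNAPII"
        )

    def test_ep_edge_and_count(self):
        net = el.build_ep_network([self.loop(50_500, 51_500, 9_500, 10_500)], self.annot)
        assert net.n_edges == 1
        assert net.edges[0].edge_type == "E-P"
        assert net.enhancer_counts == {"g1": 1}

    def test_duplicate_loops_collapse(self):
        loops = [
            self.loop(50_500, 51_500, 9_500, 10_500),
            self.loop(50_200, 51_000, 9_800, 10_200),
        ]
        net = el.build_ep_network(loops, self.annot)
        assert net.n_edges == 1
        assert len(net.edges[0].loop_indices) == 2

    def test_pp_edge(self):
        net = el.build_ep_network(
            [self.loop(9_500, 10_500, 199_500, 200_500)], self.annot
        )
        assert net.edges[0].edge_type == "P-P"
        assert net.edges[0].gene_ids == ("g1", "g2")
        assert net.enhancer_counts == {}

    def test_none_anchor_yields_no_edge(self):
        net = el.build_ep_network([self.loop(300_000, 301_000, 9_500, 10_500)], self.annot)
        assert net.n_edges == 0

    def test_removing_a_loop_never_adds_edges(self):
        loops = [
            self.loop(50_500, 51_500, 9_500, 10_500),
            self.loop(9_500, 10_500, 199_500, 200_500),
        ]
        full = el.build_ep_network(loops, self.annot)
        for drop in range(len(loops)):
            sub = el.build_ep_network(
                [lp for i, lp in enumerate(loops) if i != drop], self.annot
            )
            assert sub.n_edges <= full.n_edges
            full_keys = {(e.node_a, e.node_b) for e in full.edges}
            assert {(e.node_a, e.node_b) for e in sub.edges} <= full_keys

    def test_zero_noise_enhancer_counts_match_truth(self, noiseless_bundle):
        from epiloop import elements

        b = noiseless_bundle
        genes = b.genes
        for state in ("A", "B"):
            strengths = {
                g.gene_id: elements.promoter_strength_score(
                    g,
                    SignalTrack(b.signals[state]["H3K4me3"]),
                    SignalTrack(b.signals[state]["H3K4me1"]),
                )
                for g in genes
            }
            enhancers = elements.build_enhancer_elements(
                b.peaks[state]["H3K4me1"], genes, b.loops[state]["RNAPII"],
                other_marks={
                    "H3K27ac": b.peaks[state]["H3K27ac"],
                    "H3K27me3": b.peaks[state]["H3K27me3"],
                },
            )
            annot = elements.AnchorAnnotator(genes, strengths, enhancers)
            net = elements.build_ep_network(b.loops[state]["RNAPII"], annot)
            truth = b.truth.ep_edges
            expected = (
                truth[truth.state == state].groupby("gene_id").size().to_dict()
            )
            # a P-P partner with an enhancer-like promoter counts as an
            # extra connected enhancer for its mate
            klass = dict(
                zip(b.truth.promoter_class.gene_id, b.truth.promoter_class.klass)
            )
            pp = b.truth.pp_pairs
            for row in pp[pp.state == state].itertuples():
                for me, mate in ((row.gene_a, row.gene_b), (row.gene_b, row.gene_a)):
                    if klass[mate] == "enhancer_like":
                        expected[me] = expected.get(me, 0) + 1
            got = {
                g: c for g, c in net.enhancer_counts.items() if g in expected
            }
            assert got == expected


class TestEnhancerCountEffect:
    def network(self, counts):
        return el.EPNetwork([], dict(counts))

    def test_planted_monotone_effect(self):
        rng = np.random.default_rng(6)
        counts, expr = {}, {}
        for i in range(150):
            c = 1 + i % 3
            gid = f"g{i}"
            counts[gid] = c if c < 3 else 3 + (i % 2)
            expr[gid] = float(10 * 2 ** (c + rng.normal(0, 0.3)))
        res = el.enhancer_count_effect(self.network(counts), expr)
        assert res["medians"][">=3"] > res["medians"]["1"]
        assert res["pvalues"][("1", ">=3")] < 0.05

    def test_null_has_no_effect(self):
        rng = np.random.default_rng(7)
        counts = {f"g{i}": 1 + i % 3 for i in range(90)}
        expr = {f"g{i}": float(rng.lognormal(3, 1)) for i in range(90)}
        res = el.enhancer_count_effect(self.network(counts), expr)
        assert res["pvalues"][("1", ">=3")] > 0.001  # no tiny p under the null

    def test_empty_stratum_reports_na(self):
        counts = {"g1": 1, "g2": 1, "g3": 3, "g4": 3}
        expr = {g: 1.0 * i for i, g in enumerate(counts, 1)}
        res = el.enhancer_count_effect(el.EPNetwork([], counts), expr)
        assert res["pvalues"][("1", "2")] is None
        assert res["pvalues"][("1", ">=3")] is not None
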