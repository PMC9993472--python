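"""Domain clustering, anchor genes, and compartment calling."""

import numpy as np
import pytest

from epiloop import synth
from epiloop import topology as tp
from epiloop.types import GeneModel, GenomicInterval, Loop


def make_loop(a0, a1, b0, b1, chrom="chr1", factor="RNAPII", pet=2):
    return Loop.make(
        GenomicInterval(chrom, a0, a1), GenomicInterval(chrom, b0, b1), pet, factor
    )


def brute_force_components(loops, merge_gap=0):
    """O(n^2) all-anchor-pairs oracle for loop connectivity."""
    n = len(loops)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    def near(x, y):
        return (
            x.chrom == y.chrom
            and x.start <= y.end + merge_gap
            and y.start <= x.end + merge_gap
        )

    for i in range(n):
        for j in range(i + 1, n):
            anchors_i = (loops[i].anchor_a, loops[i].anchor_b)
            anchors_j = (loops[j].anchor_a, loops[j].anchor_b)
            if any(near(x, y) for x in anchors_i for y in anchors_j):
                parent[find(j)] = find(i)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestDomainClustering:
    def test_shared_anchor_chain(self):
        loops = [make_loop(0, 1000, 5000, 6000), make_loop(5500, 6500, 9000, 10000)]
        (dom,) = tp.cluster_loops_into_domains(loops)
        assert (dom.span.start, dom.span.end) == (0, 10000)
        assert dom.kind == "RAID"

    def test_disconnected_loops(self):
        loops = [make_loop(0, 1000, 5000, 6000), make_loop(10**6, 10**6 + 1000, 2 * 10**6, 2 * 10**6 + 1000)]
        doms = tp.cluster_loops_into_domains(loops)
        assert len(doms) == 2

    def test_mixed_factors_rejected(self):
        loops = [
            make_loop(0, 1000, 5000, 6000, factor="RNAPII"),
            make_loop(0, 1000, 5000, 6000, factor="CTCF"),
        ]
        with pytest.raises(ValueError):
            tp.cluster_loops_into_domains(loops)

    @pytest.mark.parametrize("merge_gap", [0, 500])
    def test_matches_all_pairs_oracle(self, merge_gap):
        rng = np.random.default_rng(21)
        for _ in range(8):
            loops = []
            for _ in range(50):
                chrom = f"chr{rng.integers(1, 3)}"
                s1 = int(rng.integers(0, 50_000))
                s2 = int(rng.integers(0, 50_000))
                loops.append(
                    make_loop(s1, s1 + int(rng.integers(200, 2000)),
                              s2, s2 + int(rng.integers(200, 2000)), chrom=chrom)
                )
            doms = tp.cluster_loops_into_domains(loops, merge_gap=merge_gap)
            got = {frozenset(d.member_loops) for d in doms}
            assert got == brute_force_components(loops, merge_gap)

    def test_partition_and_order_invariance(self):
        rng = np.random.default_rng(33)
        loops = []
        for _ in range(60):
            s1, s2 = (int(x) for x in rng.integers(0, 30_000, 2))
            loops.append(make_loop(s1, s1 + 800, s2, s2 + 800))
        base = tp.cluster_loops_into_domains(loops)
        assert sorted(i for d in base for i in d.member_loops) == list(range(60))
        base_sets = {
            frozenset((loops[i].anchor_a.start, loops[i].anchor_b.start) for i in d.member_loops)
            for d in base
        }
        for _ in range(20):
            perm = rng.permutation(60)
            shuffled = [loops[i] for i in perm]
            doms = tp.cluster_loops_into_domains(shuffled)
            got = {
                frozenset(
                    (shuffled[i].anchor_a.start, shuffled[i].anchor_b.start)
                    for i in d.member_loops
                )
                for d in doms
            }
            assert got == base_sets

    def test_zero_noise_memberships_match_truth(self, noiseless_bundle):
        b = noiseless_bundle
        genes = b.genes
        for state in ("A", "B"):
            doms = tp.cluster_loops_into_domains(b.loops[state]["RNAPII"])
            tp.assign_genes_to_domains(doms, genes)
            got = {
                (",".join(sorted(d.gene_ids)), d.gene_class)
                for d in doms
                if d.gene_ids
            }
            truth = b.truth.domains
            expected = {
                (row.domain_genes, row.gene_class)
                for row in truth[truth.state == state].itertuples()
            }
            assert got == expected


class TestGeneAssignment:
    domain = tp.InteractionDomain(
        "d0", "RNAPII", GenomicInterval("chr1", 1000, 9000), [0]
    )

    def gene(self, tss, gid="g"):
        return GeneModel(gid, gid, GenomicInterval("chr1", tss, tss + 100, "+"), "+")

    def test_tss_containment(self):
        mapping, frac = tp.assign_genes_to_domains([self.domain], [self.gene(5000)])
        assert mapping["g"] == "d0" and frac == 1.0

    def test_half_open_boundary(self):
        mapping, frac = tp.assign_genes_to_domains([self.domain], [self.gene(9000)])
        assert mapping["g"] == "outside" and frac == 0.0

    def test_multi_gene_class(self):
        genes = [self.gene(2000, "g1"), self.gene(4000, "g2"), self.gene(6000, "g3")]
        tp.assign_genes_to_domains([self.domain], genes)
        assert self.domain.gene_class == "MG"

    def test_subset_fraction(self):
        genes = [self.gene(2000, "in1"), self.gene(50_000, "out1")]
        _, frac = tp.assign_genes_to_domains([self.domain], genes, subset=["out1"])
        assert frac == 0.0


class TestAnchorGenes:
    def gene(self, tss, gid="g"):
        return GeneModel(gid, gid, GenomicInterval("chr1", tss, tss + 100, "+"), "+")

    def test_anchor_at_tss(self):
        loops = [make_loop(4500, 5200, 50_000, 51_000, factor="CTCF")]
        counts = tp.genes_with_anchor_at_tss(loops, [self.gene(5000)])
        assert counts == {"g": 1}

    def test_both_anchors_counted_once_per_gene(self):
        loops = [make_loop(4500, 5200, 5300, 6000, factor="CTCF")]
        counts = tp.genes_with_anchor_at_tss(loops, [self.gene(5000)])
        assert counts == {"g": 2}

    def test_no_loops(self):
        assert tp.genes_with_anchor_at_tss([], [self.gene(5000)]) == {}


class TestCompartments:
    def test_block_matrix_recovers_planted_classes(self):
        m, classes, dens = synth.make_block_contact_matrix(n_bins=20, noise_sd=0.05, seed=0)
        track = tp.call_compartments(m, 100_000, dens)
        got = np.array([1 if lab == "A" else 0 for lab in track.labels])
        assert np.array_equal(got, classes)

    def test_uniform_matrix_is_degenerate(self):
        m = np.ones((10, 10))
        track = tp.call_compartments(m, 100_000, np.ones(10))
        assert set(track.labels) == {"NA"}
        assert track.eigenvalue_fraction == 0.0

    def test_orientation_follows_gene_density(self):
        m, classes, dens = synth.make_block_contact_matrix(n_bins=20, noise_sd=0.0, seed=1)
        flipped = np.where(classes == 1, 0.0, 10.0)  # density now favors class 0
        track = tp.call_compartments(m, 100_000, flipped)
        got = np.array([1 if lab == "A" else 0 for lab in track.labels])
        assert np.array_equal(got, 1 - classes)

    def test_zero_marginal_bins_are_na(self):
        m, classes, dens = synth.make_block_contact_matrix(n_bins=20, seed=2)
        m[3, :] = 0.0
        m[:, 3] = 0.0
        track = tp.call_compartments(m, 100_000, dens)
        assert track.labels[3] == "NA"

    def test_all_zero_matrix_is_error(self):
        with pytest.raises(ValueError):
            tp.call_compartments(np.zeros((5, 5)), 100_000, np.ones(5))


class TestCompartmentSwitch:
    def gene(self, tss, gid="g"):
        return GeneModel(gid, gid, GenomicInterval("chr1", tss, tss + 100, "+"), "+")

    def test_switch_classes(self):
        ta = tp.CompartmentTrack(100, ["B", "A", "NA"], 0.5)
        tb = tp.CompartmentTrack(100, ["A", "A", "A"], 0.5)
        genes = [self.gene(50, "g1"), self.gene(150, "g2"), self.gene(250, "g3")]
        classes, frac = tp.compartment_switch(ta, tb, genes)
        assert classes == {"g1": "B->A", "g2": "stable", "g3": "NA"}
        assert frac == pytest.approx(1 / 3)

    def test_identical_tracks_all_stable(self):
        t = tp.CompartmentTrack(100, ["A", "B"], 0.5)
        classes, frac = tp.compartment_switch(t, t, [self.gene(50), ])
        assert classes == {"g": "stable"} and frac == 0.0

    def test_binsize_mismatch(self):
        with pytest.raises(ValueError):
            tp.compartment_switch(
                tp.CompartmentTrack(100, ["A"], 0.5),
                tp.CompartmentTrack(200, ["A"], 0.5),
                [],
            )
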