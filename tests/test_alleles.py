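"""Allele-group classification, segment identity, MDS, and trees."""

import itertools

import numpy as np
import pytest

from mhce.alleles import (AlleleSequence, classical_mds,
                          classify_allele_group, detect_exon6_deletion,
                          detect_group_linkage, detect_ltr_insertion,
                          jc_distance, ml_refine, nj_tree,
                          pairwise_segment_identity, _log_likelihood,
                          _leaf_vectors, _site_patterns,
                          sequence_divergence)
from mhce.simulate import toy_repeat_library


@pytest.fixture(scope="module")
def library():
    return toy_repeat_library()


@pytest.fixture(scope="module")
def ref(cohort):
    return cohort.amplicon_ref


class TestLtrDetection:
    def test_planted_ltr_found_at_offset(self, cohort, library):
        hit = detect_ltr_insertion(cohort.g2ltr_ancestor, library)
        assert hit is not None
        pos, length = hit
        assert abs(pos - 20) <= 5
        assert abs(length - 700) <= 10

    def test_clean_allele_has_no_hit(self, ref, library):
        assert detect_ltr_insertion(ref, library) is None

    def test_short_fragment_below_min_length(self, ref, library):
        planted = ref[:20] + library["LTR5B"][:300] + ref[20:]
        assert detect_ltr_insertion(planted, library,
                                    min_length=500) is None
        assert detect_ltr_insertion(planted, library,
                                    min_length=250) is not None


class TestExon6Deletion:
    E6 = None

    def e6(self, bundle):
        loc = bundle.locus
        s = loc.amplicon[0]
        return (loc.exon6[0] - s, loc.exon6[1] - s)

    def test_planted_deletion_reported(self, default_bundle, cohort):
        e6 = self.e6(default_bundle)
        hit = detect_exon6_deletion(cohort.g3_allele, cohort.amplicon_ref,
                                    e6)
        assert hit is not None
        pos, length = hit
        assert length == default_bundle.config.g3_deletion_length
        assert pos <= e6[0]

    def test_deletion_elsewhere_not_reported(self, default_bundle, ref):
        e6 = self.e6(default_bundle)
        elsewhere = ref[:100] + ref[700:]       # 600 bp gone near the 5' end
        assert detect_exon6_deletion(elsewhere, ref, e6) is None

    def test_indel_free_allele_none(self, default_bundle, ref):
        assert detect_exon6_deletion(ref, ref,
                                     self.e6(default_bundle)) is None


class TestClassification:
    def classify(self, bundle, seq, segments=None):
        coh = bundle.cohort
        loc = bundle.locus
        e6 = (loc.exon6[0] - loc.amplicon[0],
              loc.exon6[1] - loc.amplicon[0])
        allele = AlleleSequence("x", "a", seq, segments=segments or {})
        return classify_allele_group(
            allele, [coh.amplicon_ref],
            {"LTR5B": loc.repeat_library["LTR5B"]},
            coh.amplicon_ref, e6)

    def test_five_percent_divergence_is_g2(self, default_bundle, cohort):
        call = self.classify(default_bundle, cohort.g2_ancestor)
        assert call.group == "G2"
        assert 0.02 <= call.divergence_to_g1 <= 0.10

    def test_low_divergence_is_g1(self, default_bundle, cohort, rng):
        seq = list(cohort.amplicon_ref)
        for p in rng.choice(len(seq), size=int(0.005 * len(seq)),
                            replace=False):
            seq[p] = "A" if seq[p] != "A" else "C"
        call = self.classify(default_bundle, "".join(seq))
        assert call.group == "G1"

    def test_ltr_takes_precedence_over_divergence(self, default_bundle,
                                                  cohort):
        call = self.classify(default_bundle, cohort.g2ltr_ancestor)
        assert call.group == "G2_LTR"
        assert call.ltr_hit is not None

    def test_excess_divergence_unassigned_with_warning(self,
                                                       default_bundle,
                                                       cohort, rng):
        seq = "".join(rng.choice(list("ACGT"), len(cohort.amplicon_ref)))
        with pytest.warns(UserWarning):
            call = self.classify(default_bundle, seq)
        assert call.group == "unassigned"

    def test_cohort_typing_is_perfect(self, default_bundle):
        from mhce.pipeline import run_typing
        res = run_typing(default_bundle)
        assert res["accuracy"] == 1.0
        assert all(res["linkage"][g]["complete_linkage"]
                   for g in ("G2", "G2_LTR", "G3"))


class TestSegmentIdentity:
    def test_identical_sequences_give_ones(self):
        m = pairwise_segment_identity(["ACGTAC", "ACGTAC", "ACGTAC"])
        assert np.allclose(m, 1.0)

    def test_direct_mismatch_count(self):
        a = "A" * 100
        b = "A" * 95 + "C" * 5
        m = pairwise_segment_identity([a, b])
        assert np.isclose(m[0, 1], 0.95)
        assert np.allclose(m, m.T)

    def test_terminal_gaps_excluded(self):
        a = "--ACGT"
        b = "CCACGT"
        m = pairwise_segment_identity([a, b])
        assert np.isclose(m[0, 1], 1.0)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            pairwise_segment_identity(["ACGT", "ACGT"], segment=(2, 2))


class TestClassicalMds:
    def test_identical_points_collapse_to_origin(self):
        coords = classical_mds(np.ones((4, 4)))
        assert np.allclose(coords, 0.0)

    def test_two_points_separated_by_their_distance(self):
        m = np.array([[1.0, 0.9], [0.9, 1.0]])
        coords = classical_mds(m, dims=2)
        d = np.linalg.norm(coords[0] - coords[1])
        assert np.isclose(d, 0.1, atol=1e-9)

    def test_euclidean_inputs_reproduced_exactly(self):
        # 3 points on a line: distances 0.1, 0.2, 0.3
        dist = np.array([[0.0, 0.1, 0.3],
                         [0.1, 0.0, 0.2],
                         [0.3, 0.2, 0.0]])
        coords = classical_mds(1.0 - dist, dims=2)
        for i, j in itertools.combinations(range(3), 2):
            assert np.isclose(np.linalg.norm(coords[i] - coords[j]),
                              dist[i, j], atol=1e-9)


class TestJukesCantor:
    def test_zero_and_closed_form(self):
        assert jc_distance(0.0) == 0.0
        assert np.isclose(jc_distance(0.05), 0.05175, atol=5e-6)

    def test_saturation_boundary_rejected(self):
        with pytest.raises(ValueError):
            jc_distance(0.75)


class TestNeighborJoining:
    def test_two_taxa_split_evenly(self):
        t = nj_tree(np.array([[0.0, 0.2], [0.2, 0.0]]), ["a", "b"])
        assert np.isclose(t.distance("a", "b"), 0.2)
        mid = [n for n in t.adj if n not in ("a", "b")][0]
        assert np.isclose(t.edge_length("a", mid), 0.1)

    def test_additive_matrices_recovered_exactly(self):
        # 4-taxon additive tree: ((a:1,b:2):1,(c:3,d:4))
        d4 = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0]], dtype=float)
        t = nj_tree(d4, list("abcd"))
        for i, x in enumerate("abcd"):
            for j, y in enumerate("abcd"):
                if i < j:
                    assert np.isclose(t.distance(x, y), d4[i, j])
        # 5-taxon caterpillar
        d5 = np.zeros((5, 5))
        pos = [0.0, 1.0, 2.5, 4.0, 6.0]   # leaves hanging off a path
        hang = [0.5, 0.3, 0.7, 0.2, 0.4]
        for i in range(5):
            for j in range(5):
                if i != j:
                    d5[i, j] = abs(pos[i] - pos[j]) + hang[i] + hang[j]
        t5 = nj_tree(d5, list("vwxyz"))
        for i, x in enumerate("vwxyz"):
            for j, y in enumerate("vwxyz"):
                if i < j:
                    assert np.isclose(t5.distance(x, y), d5[i, j])

    def test_zero_matrix_star_with_zero_branches(self):
        t = nj_tree(np.zeros((4, 4)), list("abcd"))
        assert all(np.isclose(ln, 0.0) for _, _, ln in t.edges())

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((1, 1)), ["a"])


def _simulate_jc(tree, root_leaves, length, rng):
    """Evolve sequences down a tree topology under Jukes–Cantor."""
    bases = "ACGT"
    nodes = list(tree.adj)
    root = nodes[0]
    seqs = {root: rng.integers(0, 4, size=length)}
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        for child in tree.adj[node]:
            if child == parent:
                continue
            t = tree.adj[node][child]
            p_change = 0.75 * (1 - np.exp(-4 * t / 3))
            seq = seqs[node].copy()
            flip = rng.random(length) < p_change
            seq[flip] = (seq[flip] + rng.integers(1, 4, size=flip.sum())) % 4
            seqs[child] = seq
            stack.append((child, node))
    return {leaf: "".join(bases[i] for i in seqs[leaf])
            for leaf in tree.leaves}


class TestMlRefine:
    def test_identical_sequences_return_input_topology(self):
        t = nj_tree(np.zeros((4, 4)) + 0.1 - 0.1 * np.eye(4), list("abcd"))
        aln = {lf: "ACGTACGTAC" for lf in "abcd"}
        out = ml_refine(t, aln)
        assert out.splits() == t.splits()

    def test_likelihood_never_decreases(self, rng):
        from mhce.alleles import Tree
        truth = Tree()
        truth.leaves = list("abcdef")
        for i, lf in enumerate("abcdef"):
            truth.add_edge(lf, 100 + i // 2, 0.05)
        truth.add_edge(100, 103, 0.08)
        truth.add_edge(101, 103, 0.08)
        truth.add_edge(102, 103, 0.08)
        aln = _simulate_jc(truth, truth.leaves, 400, rng)
        start = nj_tree(np.full((6, 6), 0.3) - 0.3 * np.eye(6),
                        list("abcdef"))
        patterns = _site_patterns(aln, sorted(start.leaves))
        vecs, counts = _leaf_vectors(patterns, sorted(start.leaves))
        ll0 = _log_likelihood(start, vecs, counts)
        out = ml_refine(start, aln)
        assert out.log_likelihood >= ll0 - 1e-6

    def test_generating_topology_recovered(self, rng):
        from mhce.alleles import Tree
        truth = Tree()
        truth.leaves = list("abcdef")
        # binary caterpillar: (((a,b),c),d,(e,f)) unrooted
        truth.add_edge("a", 10, 0.04)
        truth.add_edge("b", 10, 0.05)
        truth.add_edge("c", 11, 0.04)
        truth.add_edge("d", 12, 0.06)
        truth.add_edge("e", 13, 0.05)
        truth.add_edge("f", 13, 0.04)
        truth.add_edge(10, 11, 0.09)
        truth.add_edge(11, 12, 0.09)
        truth.add_edge(12, 13, 0.09)
        aln = _simulate_jc(truth, truth.leaves, 2000, rng)
        # distance-based start, then NNI refinement
        leaves = sorted(truth.leaves)
        n = len(leaves)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                p = sequence_divergence(aln[leaves[i]], aln[leaves[j]])
                d[i, j] = d[j, i] = jc_distance(p)
        out = ml_refine(nj_tree(d, leaves), aln)
        assert out.splits() == truth.splits()

    def test_zero_column_alignment_rejected(self):
        t = nj_tree(np.zeros((3, 3)), list("abc"))
        with pytest.raises(ValueError):
            ml_refine(t, {lf: "" for lf in "abc"})


class TestGroupLinkage:
    def calls(self, rows):
        return {a: {"groups": set(g), "g1_subtypes": set(s)}
                for a, g, s in rows}

    def test_complete_linkage_detected(self):
        out = detect_group_linkage(self.calls([
            ("a1", ["G1", "G3"], ["X", "Y"]),
            ("a2", ["G1", "G3"], ["X"]),
            ("a3", ["G1"], ["Z"]),
        ]))
        assert out["G3"]["complete_linkage"] and out["G3"]["subtype"] == "X"

    def test_one_discordant_carrier_breaks_linkage(self):
        out = detect_group_linkage(self.calls([
            ("a1", ["G1", "G3"], ["X"]),
            ("a2", ["G1", "G3"], ["Y"]),
        ]))
        assert not out["G3"]["complete_linkage"]

    def test_absent_group_not_evaluable(self):
        out = detect_group_linkage(self.calls([("a1", ["G1"], ["X"])]))
        assert not out["G2"]["evaluable"]
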