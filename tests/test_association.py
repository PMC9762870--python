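"""MAF filtering, LD, variant clustering, exact tests, FDR, association
scans, hydropathy, and variant-effect tallies."""

import itertools
import math

import numpy as np
import pytest

from mhce.association import (VariantRecord, bh_fdr, cluster_variants,
                              count_variant_effects, duplication_association,
                              fisher_exact_2x2, fisher_exact_rxc,
                              genotype_association_scan, hydropathy_profile,
                              ld_matrix, ld_pair, maf_filter)


def variant(genotypes, vid="v", pos=0, vtype="SNP", ref="A", alt="C"):
    return VariantRecord(variant_id=vid, position=pos, vtype=vtype,
                         ref=ref, alt=alt, genotypes=genotypes)


class TestMafFilter:
    def test_strict_threshold(self):
        at_threshold = variant([1] * 2 + [0] * 8)       # MAF 0.1
        above = variant([1] * 2 + [0] * 8 + [1])        # MAF 0.136
        mono = variant([0] * 10)
        kept = maf_filter([at_threshold, above, mono], threshold=0.1)
        assert kept == [above]


class TestLdPair:
    def test_full_coupling(self):
        res = ld_pair([1, 1, 0, 0], [1, 1, 0, 0])
        assert np.isclose(res.D, 0.25) and np.isclose(res.r, 1.0)

    def test_independence(self):
        res = ld_pair([1, 1, 0, 0], [1, 0, 1, 0])
        assert res.D == 0.0 and res.r == 0.0

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            ld_pair([1, 1, 1], [1, 0, 1])

    def test_bounds_on_all_small_haplotype_sets(self):
        """Oracle: direct frequency counting over every biallelic
        composition of n <= 8 haplotypes."""
        for n in range(2, 9):
            for hapA in itertools.product([0, 1], repeat=n):
                if len(set(hapA)) < 2:
                    continue
                for hapB in itertools.product([0, 1], repeat=n):
                    if len(set(hapB)) < 2:
                        continue
                    res = ld_pair(hapA, hapB)
                    pa = sum(hapA) / n
                    pb = sum(hapB) / n
                    pab = sum(a & b for a, b in zip(hapA, hapB)) / n
                    assert np.isclose(res.D, pab - pa * pb)
                    assert abs(res.r) <= 1 + 1e-12
                    assert -min(pa * pb, (1 - pa) * (1 - pb)) - 1e-12 \
                        <= res.D <= min(pa * (1 - pb),
                                        (1 - pa) * pb) + 1e-12


class TestClusterVariants:
    def test_perfect_triple_is_one_complete_cluster(self):
        r = np.ones((3, 3))
        (cl,) = cluster_variants(r, ["a", "b", "c"])
        assert cl.members == ["a", "b", "c"] and cl.complete_ld

    def test_imperfect_pair_split_into_singletons(self):
        r = np.array([[1.0, 0.95], [0.95, 1.0]])
        clusters = cluster_variants(r, ["a", "b"])
        assert sorted(c.members for c in clusters) == [["a"], ["b"]]

    def test_block_diagonal_gives_two_clusters(self):
        r = np.zeros((5, 5))
        r[:3, :3] = 1.0
        r[3:, 3:] = 1.0
        np.fill_diagonal(r, 1.0)
        clusters = cluster_variants(r, list("abcde"))
        assert sorted(sorted(c.members) for c in clusters) == \
            [["a", "b", "c"], ["d", "e"]]

    def test_empty_input(self):
        assert cluster_variants(np.zeros((0, 0)), []) == []

    def test_cohort_cluster_recovery(self, default_bundle):
        from mhce.pipeline import run_association
        res = run_association(default_bundle)
        coh = default_bundle.cohort
        truth_clusters = {}
        for k, c in enumerate(coh.variant_cluster):
            if c >= 0:
                truth_clusters.setdefault(c, set()).add(f"v{k:03d}")
        found = {frozenset(c.members) for c in res["clusters"]}
        for members in truth_clusters.values():
            assert frozenset(members) in found
        sizes = sorted((c.size for c in res["clusters"]), reverse=True)
        assert sizes[:2] == [21, 18]


def fisher_enumeration_oracle(table):
    """Exhaustive hypergeometric enumeration for a 2x2 table."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_prob(x):
        return (math.lgamma(r1 + 1) + math.lgamma(r2 + 1)
                + math.lgamma(c1 + 1) + math.lgamma(n - c1 + 1)
                - math.lgamma(n + 1)
                - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
                - math.lgamma(c1 - x + 1) - math.lgamma(r2 - c1 + x + 1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = log_prob(a)
    return sum(math.exp(log_prob(x)) for x in range(lo, hi + 1)
               if log_prob(x) <= obs + 1e-7)


class TestFisher2x2:
    def test_cohort_worked_example(self):
        assert round(fisher_exact_2x2([[0, 22], [6, 16]]), 2) == 0.02

    def test_symmetric_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0

    def test_diagonal_enumeration(self):
        assert np.isclose(fisher_exact_2x2([[2, 0], [0, 2]]), 1 / 3)

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(200):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert np.isclose(fisher_exact_2x2(t),
                              fisher_enumeration_oracle(t), rtol=1e-6)


class TestFisherRxC:
    def test_two_by_two_delegates(self, rng):
        for _ in range(25):
            t = rng.integers(1, 10, size=(2, 2))
            assert np.isclose(fisher_exact_rxc(t), fisher_exact_2x2(t))

    def test_hand_enumeration_three_by_two(self):
        # margins: rows (1,1,1), cols (2,1); 3 tables with equal
        # probability 1/3 each -> p sums all with prob <= observed = 1
        assert np.isclose(fisher_exact_rxc([[1, 0], [0, 1], [1, 0]]), 1.0)

    def test_unbalanced_three_by_two(self):
        t = [[4, 0], [0, 4], [2, 2]]
        p = fisher_exact_rxc(t)
        assert 0 < p < 0.2

    def test_all_zero_row_dropped(self):
        assert np.isclose(fisher_exact_rxc([[3, 1], [0, 0], [1, 3]]),
                          fisher_exact_2x2([[3, 1], [1, 3]]))

    def test_monte_carlo_close_to_exact(self):
        t = [[6, 2], [1, 5], [3, 3]]
        exact = fisher_exact_rxc(t)
        mc = fisher_exact_rxc(t, monte_carlo=True, n_samples=20000, seed=0)
        assert abs(exact - mc) < 0.02


class TestBhFdr:
    def test_step_up_examples(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(bh_fdr([0.5]), [0.5])
        assert np.allclose(bh_fdr([0.04, 1.0]), [0.08, 1.0])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=40)
        q = bh_fdr(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_empty_vector(self):
        assert bh_fdr([]).size == 0


class TestAssociationScan:
    def test_planted_penetrant_variant_attains_min_q(self, rng):
        n = 40
        outcome = np.array(["protected"] * 20 + ["not_protected"] * 20)
        genos = {"null%d" % k: rng.integers(0, 3, size=n)
                 for k in range(5)}
        genos["planted"] = np.where(outcome == "protected", 0, 2)
        res = genotype_association_scan(genos, outcome)
        by_name = {r.name: r for r in res}
        assert by_name["planted"].q == min(r.q for r in res)
        assert by_name["planted"].p < 1e-6

    def test_uninformative_cluster_flagged(self):
        outcome = np.array(["protected", "not_protected"] * 5)
        res = genotype_association_scan({"const": np.zeros(10, int)},
                                        outcome)
        assert res[0].p == 1.0 and "uninformative" in res[0].flags

    def test_empty_scope_rejected(self):
        with pytest.raises(ValueError):
            genotype_association_scan({"v": np.zeros(4, int)},
                                      np.array(["a"] * 4),
                                      scope=np.zeros(4, bool))


class TestDuplicationAssociation:
    def test_cohort_g2ltr_example(self, default_bundle):
        from mhce.pipeline import run_association
        res = run_association(default_bundle)
        assert round(res["g2ltr"].p, 2) == 0.02

    def test_independent_construction_near_uniform(self, rng):
        # duplication independent of outcome: p should not concentrate low
        ps = []
        for _ in range(50):
            groups = {f"a{i}": ({"G1", "G3"} if rng.random() < 0.4
                                else {"G1"}) for i in range(40)}
            outcome = np.array(rng.choice(["protected", "not_protected"],
                                          size=40))
            ps.append(duplication_association(groups, outcome).p)
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_all_duplicated_uninformative(self):
        groups = {f"a{i}": {"G1", "G3"} for i in range(10)}
        outcome = np.array(["protected", "not_protected"] * 5)
        res = duplication_association(groups, outcome)
        assert res.p == 1.0 and "uninformative" in res.flags


class TestHydropathy:
    def test_constant_profiles(self):
        pos, scores = hydropathy_profile("I" * 21)
        assert np.allclose(scores, 4.5)
        _, scores_r = hydropathy_profile("R" * 21)
        assert np.allclose(scores_r, -4.5)

    def test_normalized_position_range(self):
        pos, scores = hydropathy_profile("ILVFMCAGTSWYPHQNEDKR")
        assert pos[0] == 0.0 and pos[-1] == 1.0
        assert len(scores) == 20

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_profile("ILV", window=9)


class TestVariantEffects:
    REF = "TTT" + "ATGGCTGCTAAGGCTGCT" + "TAA" + "GGG"
    #      5'UTR  M  A  A  K  A  A     stop    3'UTR
    REGIONS = [("5pUTR", (0, 3)), ("CDS", (3, 24)), ("3pUTR", (24, 27))]

    def run(self, variants):
        return count_variant_effects(variants, self.REF, cds_start=3,
                                     cds_end=24, regions=self.REGIONS)

    def test_synonymous_snp_not_a_sap(self):
        v = variant([0], vid="s", pos=11, alt="A")   # GCT -> GCA (Ala)
        out = self.run([v])
        assert out["tallies"]["CDS"]["SNP"] == 1
        assert out["sap_count"] == 0

    def test_utr_snp_region_tally_only(self):
        v = variant([0], vid="u", pos=25, alt="C")
        out = self.run([v])
        assert out["tallies"]["3pUTR"]["SNP"] == 1
        assert out["sap_count"] == 0

    def test_identical_amino_changes_deduplicated(self):
        # both SNPs turn codon 2 GCT into CCT (Pro) vs TCT (Ser)? use same
        # change from different records at the same site
        v1 = variant([0], vid="a", pos=6, alt="C")   # GCT -> CCT (A2P)
        v2 = variant([0], vid="b", pos=6, alt="C")
        out = self.run([v1, v2])
        assert out["sap_count"] == 1

    def test_outside_regions_rejected(self):
        with pytest.raises(ValueError):
            self.run([variant([0], vid="x", pos=99)])
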