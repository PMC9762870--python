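"""Coverage trimming, k-mer masking, base calling, block phasing and
merging, conflict screening, haplotig expansion and allele integration."""


import numpy as np
import pytest

from mhce.phasing import (ConnectionGraph, HaplotypeBlock, VariantCall,
                          block_haplotype_coverage, call_bases,
                          collapse_haplotigs, expand_haplotigs,
                          kmer_blacklist, match_haplotigs_to_alleles,
                          merge_allele_with_utr, merge_blocks,
                          phase_blocks, pool_and_trim_coverage,
                          screen_conflicts)


class TestCoverageTrim:
    def test_ends_below_threshold_trimmed(self):
        track = np.full(100, 9999)
        track[10:90] = 20000
        lo, hi = pool_and_trim_coverage([track], min_cov=10000)
        assert (lo, hi) == (10, 90)

    def test_uniform_high_coverage_untouched(self):
        lo, hi = pool_and_trim_coverage([np.full(50, 20000)])
        assert (lo, hi) == (0, 50)

    def test_interior_dip_retained(self):
        track = np.full(100, 20000)
        track[40:60] = 5000
        assert pool_and_trim_coverage([track]) == (0, 100)

    def test_pooling_across_samples(self):
        # each sample below threshold; the pool is not
        tracks = [np.full(30, 4000), np.full(30, 7000)]
        assert pool_and_trim_coverage(tracks) == (0, 30)

    def test_all_below_threshold_is_an_error(self):
        with pytest.raises(ValueError):
            pool_and_trim_coverage([np.full(10, 5)])


class TestKmerBlacklist:
    def test_duplicated_block_masked(self, rng):
        # a position is masked only when no overlapping k-mer is unique,
        # so the copied block must exceed 2k-1 bases
        uniq = "".join(rng.choice(list("ACGT"), 400))
        block = "".join(rng.choice(list("ACGT"), 160))
        other = "".join(rng.choice(list("ACGT"), 150))
        target = uniq[:200] + block + uniq[200:]
        background = {"t": target, "elsewhere": other + block + other}
        masked = kmer_blacklist({"t": target}, background, k=76)["t"]
        assert masked == [(275, 285)]

    def test_unique_sequence_unmasked(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        assert kmer_blacklist({"t": seq}, {"t": seq}, k=76)["t"] == []

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            kmer_blacklist({"t": "ACGT"}, {"t": "ACGT" * 50}, k=76)


class TestCallBases:
    def counts(self, **kw):
        row = [kw.get(b, 0) for b in "ACGT"]
        return np.array([row])

    def test_quarter_fraction_is_heterozygous(self):
        (c,) = call_bases(self.counts(A=30, G=10))
        assert c.zygosity == "het"
        assert c.bases == ("A", "G")

    def test_low_fraction_is_homozygous(self):
        (c,) = call_bases(self.counts(A=39, G=1))
        assert c.zygosity == "hom" and c.bases == ("A",)

    def test_four_way_tie_is_ambiguous(self):
        with pytest.warns(UserWarning):
            (c,) = call_bases(self.counts(A=10, C=10, G=10, T=10))
        assert c.zygosity == "ambiguous"

    def test_threshold_is_inclusive(self):
        (c,) = call_bases(self.counts(A=75, C=25))
        assert c.zygosity == "het"


def _graph(edges, n_cis_key="cis"):
    """edges: {(i, j): (n_parallel, n_cross)} on called-base index 0/1."""
    g = ConnectionGraph()
    for (i, j), (cis, trans) in edges.items():
        mat = np.array([[cis / 2, trans / 2], [trans / 2, cis / 2]])
        g.add(0, i, j, mat)
    return g


def _het(pos, bases=("A", "C")):
    return VariantCall(position=pos, bases=bases, fractions=(0.6, 0.4),
                       zygosity="het")


class TestPhaseBlocks:
    def test_error_free_chain_recovers_truth_up_to_flip(self):
        calls = [_het(10), _het(20), _het(30)]
        g = _graph({(10, 20): (100, 0), (20, 30): (100, 0)})
        blocks = phase_blocks(g, calls)
        assert len(blocks) == 1
        b = blocks[0]
        # all three positions in the same orientation (truth is all-cis)
        os = [b.orientation[p] for p in (10, 20, 30)]
        assert os in ([0, 0, 0], [1, 1, 1])

    def test_disconnected_pairs_make_two_blocks(self):
        calls = [_het(p) for p in (10, 20, 500, 510)]
        g = _graph({(10, 20): (50, 0), (500, 510): (50, 0)})
        blocks = phase_blocks(g, calls)
        assert sorted(len(b.positions) for b in blocks) == [2, 2]

    def test_majority_configuration_wins(self):
        calls = [_het(10), _het(20)]
        g = _graph({(10, 20): (40, 60)})     # cross majority
        b = phase_blocks(g, calls)[0]
        assert b.orientation[10] != b.orientation[20]

    def test_isolated_het_becomes_singleton_block(self):
        calls = [_het(10), _het(20), _het(900)]
        g = _graph({(10, 20): (50, 0)})
        blocks = phase_blocks(g, calls)
        assert sorted(len(b.positions) for b in blocks) == [1, 2]


class TestScreenConflicts:
    def block(self):
        calls = {p: _het(p) for p in (10, 20, 30)}
        return HaplotypeBlock(positions=[10, 20, 30],
                              orientation={10: 0, 20: 0, 30: 0},
                              calls=calls)

    def test_high_average_conflict_demoted(self):
        g = _graph({(10, 20): (112, 38), (10, 30): (113, 37),
                    (20, 30): (150, 0)})
        out = screen_conflicts(self.block(), g)
        # variant 10 averages 25% conflict across two 150-read edges
        assert 10 in out.ambiguous and 10 not in out.positions
        assert {20, 30} <= set(out.positions)

    def test_moderate_conflict_retained(self):
        g = _graph({(10, 20): (127, 23), (10, 30): (128, 22),
                    (20, 30): (150, 0)})
        out = screen_conflicts(self.block(), g)
        assert out.positions == [10, 20, 30]

    def test_low_support_edges_leave_variant_unevaluated(self):
        g = _graph({(10, 20): (40, 10), (20, 30): (150, 0)})
        out = screen_conflicts(self.block(), g, min_support=100)
        assert 10 in out.positions and 10 in out.unevaluated


class TestMergeBlocks:
    def blocks(self):
        b1 = HaplotypeBlock(positions=[10], orientation={10: 0},
                            calls={10: _het(10)})
        b2 = HaplotypeBlock(positions=[500], orientation={500: 0},
                            calls={500: _het(500)})
        return b1, b2

    def coverage_fn(self, pattern):
        """pattern: list over samples of +1 (concordant) / -1 / 0 (tie)."""
        def fn(block):
            first = min(block.positions)
            out = {}
            for s, rel in enumerate(pattern):
                if first == 10:
                    out[s] = (100, 50)
                elif rel == 0:
                    out[s] = (70, 70)
                else:
                    out[s] = (100, 50) if rel > 0 else (50, 100)
            return out
        return fn

    def test_unanimous_consensus_merges(self):
        b1, b2 = self.blocks()
        out = merge_blocks([b1, b2], self.coverage_fn([1] * 9))
        assert len(out) == 1
        assert out[0].positions == [10, 500]
        assert out[0].orientation[500] == 0

    def test_unanimous_anticorrelated_merges_flipped(self):
        b1, b2 = self.blocks()
        out = merge_blocks([b1, b2], self.coverage_fn([-1] * 9))
        assert len(out) == 1
        assert out[0].orientation[500] == 1

    def test_eight_of_nine_does_not_merge(self):
        b1, b2 = self.blocks()
        out = merge_blocks([b1, b2], self.coverage_fn([1] * 8 + [-1]))
        assert len(out) == 2

    def test_tied_sample_vetoes_merge(self):
        b1, b2 = self.blocks()
        out = merge_blocks([b1, b2], self.coverage_fn([1] * 8 + [0]))
        assert len(out) == 2

    def test_single_block_unchanged(self):
        b1, _ = self.blocks()
        assert merge_blocks([b1], lambda b: {0: (1, 2)}) == [b1]


class TestBlockCoverage:
    def test_oriented_sums(self):
        b = HaplotypeBlock(positions=[10, 20],
                           orientation={10: 0, 20: 1},
                           calls={10: _het(10), 20: _het(20)})
        depths = {0: {10: (30.0, 10.0), 20: (8.0, 25.0)}}
        cov = block_haplotype_coverage(b, depths)
        assert cov[0] == (30.0 + 25.0, 10.0 + 8.0)


class TestExpandHaplotigs:
    def test_unphased_het_gets_iupac_in_both(self):
        ref = "GGGGG"
        calls = [_het(2, ("A", "C"))]
        primary = HaplotypeBlock(positions=[], orientation={}, calls={})
        h1, h2 = expand_haplotigs(primary, calls, ref)
        assert h1[2] == h2[2] == "M"

    def test_no_hets_identical_haplotigs(self):
        ref = "GGGGG"
        calls = [VariantCall(1, ("T",), (1.0,), "hom")]
        primary = HaplotypeBlock(positions=[], orientation={}, calls={})
        h1, h2 = expand_haplotigs(primary, calls, ref)
        assert h1 == h2 == "GTGGG"

    def test_conflicting_hom_and_het_call_rejected(self):
        ref = "GGGGG"
        calls = [VariantCall(2, ("T",), (1.0,), "hom"), _het(2)]
        primary = HaplotypeBlock(positions=[], orientation={}, calls={})
        with pytest.raises(ValueError):
            expand_haplotigs(primary, calls, ref)

    def test_phased_toy_truth_recovered_up_to_swap(self):
        ref = "GGGGGGGG"
        calls = [_het(1, ("A", "C")), _het(5, ("T", "G"))]
        primary = HaplotypeBlock(
            positions=[1, 5], orientation={1: 0, 5: 1},
            calls={c.position: c for c in calls})
        h1, h2 = expand_haplotigs(primary, calls, ref)
        truth = {"GAGGGGGG"[:8], "GCGGGTGG"}
        assert {h1, h2} == {"GAGGGGGG", "GCGGGTGG"} or \
            {h1, h2} == {"GAGGGTGG"[:8], "GCGGGGGG"}
        # hap1 takes bases (A, G), hap2 (C, T): orientation respected
        assert {h1, h2} == {"GAGGGGGG", "GCGGGTGG"}


class TestHaplotigAlleleIntegration:
    def test_greedy_matches_exhaustive_on_two_by_two(self):
        haplotigs = {"H1": "AAAA", "H2": "AACC"}
        alleles = {"A1": "AAAA", "A2": "ACCC"}
        # mismatch matrix [[0, 3], [2, 1]]: greedy = (H1,A1) then (H2,A2)
        pairs = match_haplotigs_to_alleles(haplotigs, alleles)
        assert [(h, a) for h, a, _ in pairs] == [("H1", "A1"),
                                                 ("H2", "A2")]
        best_total = min(
            sum(sum(1 for x, y in zip(haplotigs[h], alleles[a]) if x != y)
                for h, a in pairing)
            for pairing in ([("H1", "A1"), ("H2", "A2")],
                            [("H1", "A2"), ("H2", "A1")]))
        assert sum(m for _, _, m in pairs) == best_total

    def test_one_haplotig_two_alleles_single_pair(self):
        pairs = match_haplotigs_to_alleles({"H1": "AAAA"},
                                           {"A1": "AAAT", "A2": "AAAA"})
        assert pairs == [("H1", "A2", 0)]

    def test_empty_inputs_empty_pairing(self):
        assert match_haplotigs_to_alleles({}, {}) == []

    def test_excluded_positions_ignored(self):
        pairs = match_haplotigs_to_alleles({"H": "AAAA"}, {"A": "AAAT"},
                                           excluded_positions={3})
        assert pairs[0][2] == 0

    def test_collapse_haplotigs_differing_only_in_utr(self):
        h = {"a_h1": "AAAACCCC", "a_h2": "AAAACCGG", "a_h3": "ATAACCCC"}
        out = collapse_haplotigs(h, utr_interval=(6, 8))
        assert set(out) == {"a_h1", "a_h3"}

    def test_merge_allele_with_utr_lengths_and_coordinates(self):
        seq, junc = merge_allele_with_utr("A" * 100, "G" * 200, "C" * 50)
        assert len(seq) == 350
        assert junc["utr_exon_start"] == 150
        with pytest.raises(ValueError):
            merge_allele_with_utr("A" * 10, "G" * 5, None)
        with pytest.warns(UserWarning):
            seq2, _ = merge_allele_with_utr("A" * 10, "", "C" * 5)
        assert len(seq2) == 15


class TestEndToEndRecovery:
    def test_synthetic_animals_recover_truth_up_to_flip(self,
                                                        default_bundle):
        from mhce.pipeline import run_phasing_animal
        from mhce.simulate import simulate_phasing_observations
        import numpy as np
        cfg = default_bundle.config
        coh = default_bundle.cohort
        animals = coh.animals[:3]
        obs = simulate_phasing_observations(
            coh, cfg, np.random.default_rng(42), animals=animals)
        for a in animals:
            res = run_phasing_animal(obs[a], coh.transcript_ref)
            truth = coh.haplotig_truth(a)
            excl = set(res.primary.ambiguous) | \
                {c.position for c in res.calls if c.zygosity == "het"
                 and c.position not in set(res.primary.positions)}
            h1, h2 = res.haplotigs
            direct = sum(1 for i, (x, y) in enumerate(zip(h1, truth[0]))
                         if x != y and i not in excl) + \
                sum(1 for i, (x, y) in enumerate(zip(h2, truth[1]))
                    if x != y and i not in excl)
            flipped = sum(1 for i, (x, y) in enumerate(zip(h1, truth[1]))
                          if x != y and i not in excl) + \
                sum(1 for i, (x, y) in enumerate(zip(h2, truth[0]))
                    if x != y and i not in excl)
            assert min(direct, flipped) == 0
            assert res.phased_fraction > 0.99
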