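"""Phylogenetic profiles, NJ trees, cores, flanking pairs, densities."""

import numpy as np
import pytest
from conftest import random_additive_tree
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix, TreeNode

from dupmosaic.mosaic import (
    DupliconOccurrence,
    GenomicInterval,
    PhyloProfile,
    build_profiles,
    compare_densities,
    complement_intervals,
    core_duplicons,
    distance_matrix,
    duplicon_weights,
    flanking_pairs,
    merge_intervals,
    nj_tree,
    profile_distance,
    shares_history,
    weighted_density,
)
from dupmosaic.simulate import generate_flanked_cnv, generate_segment_set


def _occ(dup, chrom, s, e, ident=99.0):
    return DupliconOccurrence(dup, GenomicInterval(chrom, s, e, dup), ident, e - s)


def _profile(seg, bits, index):
    return PhyloProfile(seg, np.array(bits, dtype=np.int8), tuple(index))


class TestBuildProfiles:
    def _segment_with(self, n_dups, chrom="chr1"):
        seg = GenomicInterval(chrom, 0, 10_000, f"seg_{chrom}", "SD")
        occs = [_occ(f"d{i}", chrom, 200 * i, 200 * i + 150) for i in range(n_dups)]
        return seg, occs

    def test_segment_with_twelve_duplicons_retained(self):
        seg, occs = self._segment_with(12)
        (prof,) = build_profiles([seg], occs)
        assert prof.bits.sum() == 12

    def test_segment_with_nine_duplicons_dropped(self):
        seg, occs = self._segment_with(9)
        assert build_profiles([seg], occs) == []

    def test_identity_threshold_is_strict(self):
        seg, occs = self._segment_with(10)
        occs[0] = _occ("d0", "chr1", 0, 150, ident=94.9)
        # d0 no longer qualifies -> only 9 present -> segment dropped
        assert build_profiles([seg], occs) == []

    def test_short_occurrences_do_not_count(self):
        seg, occs = self._segment_with(10)
        occs[0] = DupliconOccurrence("d0", GenomicInterval("chr1", 0, 99, "d0"), 99.0, 99)
        assert build_profiles([seg], occs) == []

    def test_absent_duplicons_dropped_from_index(self):
        seg_a, occs_a = self._segment_with(10, chrom="chrA")
        seg_b, occs_b = self._segment_with(10, chrom="chrB")
        # chrB occurrences fail identity -> segment B dropped, its duplicons too
        occs_b = [_occ(o.duplicon_id + "_b", "chrB", o.interval.start, o.interval.end, 90.0)
                  for o in occs_b]
        profs = build_profiles([seg_a, seg_b], occs_a + occs_b)
        assert [p.segment_id for p in profs] == ["seg_chrA"]
        assert all(not d.endswith("_b") for d in profs[0].index)


class TestProfileDistance:
    def test_identical_profiles(self):
        a = _profile("a", [1, 0, 1, 1], "wxyz")
        b = _profile("b", [1, 0, 1, 1], "wxyz")
        assert profile_distance(a, b) == 0.0
        assert shares_history(a, b)

    def test_complementary_profiles(self):
        a = _profile("a", [1, 0] * 4, "abcdefgh")
        b = _profile("b", [0, 1] * 4, "abcdefgh")
        assert profile_distance(a, b) == 1.0
        assert not shares_history(a, b)

    def test_half_discordant(self):
        a = _profile("a", [1, 1, 0, 0], "wxyz")
        b = _profile("b", [1, 0, 1, 0], "wxyz")
        assert profile_distance(a, b) == 0.5

    def test_mismatched_indices_rejected(self):
        with pytest.raises(ValueError):
            profile_distance(_profile("a", [1], "x"), _profile("b", [1], "y"))

    @given(st.data())
    @settings(max_examples=150, derandomize=True)
    def test_is_a_metric(self, data):
        n = data.draw(st.integers(1, 12))
        index = tuple(f"d{i}" for i in range(n))
        bits = lambda name: _profile(
            name, data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)), index)
        a, b, c = bits("a"), bits("b"), bits("c")
        dab, dba = profile_distance(a, b), profile_distance(b, a)
        assert dab == dba >= 0.0
        assert profile_distance(a, a) == 0.0
        assert dab <= profile_distance(a, c) + profile_distance(c, b) + 1e-12


class TestNjTree:
    @pytest.mark.parametrize("seed", range(12))
    def test_recovers_additive_trees_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        newick, leaves = random_additive_tree(rng, n)
        true = TreeNode.read([newick])
        dm = true.tip_tip_distances()
        rebuilt = nj_tree(DistanceMatrix(dm.data, ids=dm.ids))
        got = rebuilt.tip_tip_distances(endpoints=list(dm.ids))
        np.testing.assert_allclose(
            got.filter(dm.ids).data, dm.data, atol=1e-6)

    def test_three_leaves_closed_form(self):
        # d(ab)=3, d(ac)=4, d(bc)=5 -> branch lengths 1, 2, 3
        dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
                            ids=["a", "b", "c"])
        tree = nj_tree(dm)
        lens = {t.name: t.length for t in tree.tips()}
        assert lens == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_fewer_than_three_leaves_rejected(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_two_planted_groups_are_bipartitioned(self):
        segments, occurrences, truth = generate_segment_set(
            n_groups=2, segments_per_group=5, duplicons_per_group=15,
            sharing=0.9, seed=3)
        profiles = build_profiles(segments, occurrences)
        tree = nj_tree(distance_matrix(profiles))
        subsets = {frozenset(n.subset()) for n in tree.non_tips()}
        subsets.add(frozenset(t.name for t in tree.tips()))
        ga = frozenset(truth["group_0"][0])
        gb = frozenset(truth["group_1"][0])
        assert ga in subsets or gb in subsets


class TestCoreDuplicons:
    def _setup(self, shares_count, n_leaves=10):
        index = ("core", "other")
        leaves = [f"s{i:02d}" for i in range(n_leaves)]
        profiles = [
            _profile(s, [1 if i < shares_count else 0, 1], index)
            for i, s in enumerate(leaves)
        ]
        sub = f"({leaves[0]}:1,{leaves[1]}:1)"
        for leaf in leaves[2:]:
            sub = f"({sub}:1,{leaf}:1)"
        tree = TreeNode.read([sub + ";"])
        return tree, profiles

    def test_seven_of_ten_is_core(self):
        tree, profiles = self._setup(7)
        cores = core_duplicons(tree, profiles, share_threshold=0.67)
        root = max(cores, key=lambda c: len(c.leaves))
        assert "core" in root.core_duplicons

    def test_exactly_67_percent_is_not_core(self):
        # 67 of 100 leaves: share == 0.67 fails the strict > rule
        tree, profiles = self._setup(67, n_leaves=100)
        cores = core_duplicons(tree, profiles, share_threshold=0.67)
        root = max(cores, key=lambda c: len(c.leaves))
        assert "core" not in root.core_duplicons
        assert "other" in root.core_duplicons  # present in every leaf

    def test_threshold_zero_and_one_boundaries(self):
        tree, profiles = self._setup(3)
        root0 = max(core_duplicons(tree, profiles, 0.0), key=lambda c: len(c.leaves))
        assert set(root0.core_duplicons) == {"core", "other"}  # any presence
        root1 = max(core_duplicons(tree, profiles, 1.0), key=lambda c: len(c.leaves))
        assert root1.core_duplicons == ()  # strict >1 impossible

    def test_planted_core_detected(self):
        segments, occurrences, truth = generate_segment_set(
            n_groups=2, segments_per_group=6, duplicons_per_group=14,
            sharing=0.5, seed=8, core_fraction=0.9)
        profiles = build_profiles(segments, occurrences, min_duplicons=3)
        tree = nj_tree(distance_matrix(profiles))
        cores = core_duplicons(tree, profiles, share_threshold=0.67)
        for g in ("group_0", "group_1"):
            names, core_id = truth[g]
            found = any(
                core_id in c.core_duplicons
                for c in cores
                if set(c.leaves) <= set(names)
            )
            assert found, f"designated core of {g} not detected"


class TestFlankingPairs:
    def test_window_membership(self):
        cnv = GenomicInterval("chr1", 0, 1000, "cnv", "CNV")
        occs = [_occ("d1", "chr1", 50, 200), _occ("d1", "chr1", 900, 990)]
        # windows are [0, 250) and [750, 1000)
        assert len(flanking_pairs(cnv, occs)) == 1

    def test_middle_occurrence_does_not_pair(self):
        cnv = GenomicInterval("chr1", 0, 1000, "cnv", "CNV")
        occs = [_occ("d1", "chr1", 50, 200), _occ("d1", "chr1", 400, 500)]
        assert flanking_pairs(cnv, occs) == []

    def test_cross_product_of_window_copies(self):
        cnv = GenomicInterval("chr1", 0, 1000, "cnv", "CNV")
        lefts = [_occ("d1", "chr1", s, s + 50) for s in (0, 60, 120)]
        rights = [_occ("d1", "chr1", s, s + 50) for s in (800, 900)]
        pairs = flanking_pairs(cnv, lefts + rights)
        assert len(pairs) == 6
        assert {(a.interval.start, b.interval.start) for a, b in pairs} == {
            (l.interval.start, r.interval.start)
            for l in lefts for r in rights}

    def test_different_duplicons_do_not_pair_without_sequences(self):
        cnv = GenomicInterval("chr1", 0, 1000, "cnv", "CNV")
        occs = [_occ("d1", "chr1", 0, 100), _occ("d2", "chr1", 900, 1000)]
        assert flanking_pairs(cnv, occs) == []

    def test_sequence_mode_checks_identity_and_length_ratio(self):
        rng = np.random.default_rng(5)
        unit = "".join(rng.choice(list("ACGT"), size=100))
        filler = "".join(rng.choice(list("ACGT"), size=100))
        # chromosome: unit at [0, 100) and an identical copy at [900, 1000)
        chrom_seq = unit + filler * 8 + unit
        seqs = {"chr1": chrom_seq}
        cnv = GenomicInterval("chr1", 0, 1000, "cnv", "CNV")
        identical = [_occ("dL", "chr1", 0, 100), _occ("dR", "chr1", 900, 1000)]
        # identity passes even though the duplicon ids differ
        assert len(flanking_pairs(cnv, identical, sequences=seqs)) == 1
        divergent = [_occ("dL", "chr1", 0, 100), _occ("dR", "chr1", 800, 900)]
        assert flanking_pairs(cnv, divergent, sequences=seqs) == []
        # length ratio 100/200 = 0.5 <= 0.9 fails even with matching sequence
        long_left = [_occ("dL", "chr1", 0, 200), _occ("dR", "chr1", 900, 1000)]
        assert flanking_pairs(cnv, long_left, sequences=seqs) == []

    def test_invariant_under_coordinate_reflection(self):
        cnv, occs = generate_flanked_cnv(2000, n_pairs=3, seed=4)
        mirrored = [
            DupliconOccurrence(
                o.duplicon_id,
                GenomicInterval(o.interval.chrom, 2000 - o.interval.end,
                                2000 - o.interval.start, o.interval.name),
                o.identity, o.length)
            for o in occs
        ]
        assert len(flanking_pairs(cnv, occs)) == len(flanking_pairs(cnv, mirrored))

    def test_degenerate_cnv_rejected(self):
        with pytest.raises(ValueError):
            flanking_pairs(GenomicInterval("chr1", 0, 3, "tiny"), [])


class TestWeightedDensity:
    def test_two_occurrences_with_weights_three_and_five(self):
        region = GenomicInterval("chr1", 0, 1000, "r")
        occs = [_occ("a", "chr1", 100, 200), _occ("b", "chr1", 300, 400)]
        assert weighted_density(region, occs, {"a": 3, "b": 5}) == pytest.approx(0.008)

    def test_empty_region(self):
        region = GenomicInterval("chr1", 0, 1000, "r")
        assert weighted_density(region, [], {"a": 3}) == 0.0

    def test_exact_half_overlap_counts(self):
        region = GenomicInterval("chr1", 0, 1000, "r")
        occ = _occ("a", "chr1", 950, 1050)  # exactly 50 of 100 bases inside
        assert weighted_density(region, [occ], {"a": 2}) == pytest.approx(0.002)
        just_out = _occ("b", "chr1", 951, 1053)  # 49 of 102 inside
        assert weighted_density(region, [just_out], {"b": 2}) == 0.0

    def test_linear_in_weights(self, rng):
        region = GenomicInterval("chr1", 0, 5000, "r")
        occs = [_occ(f"d{i}", "chr1", int(s), int(s) + 120)
                for i, s in enumerate(rng.integers(0, 4800, size=10))]
        w = {f"d{i}": float(rng.integers(1, 9)) for i in range(10)}
        w2 = {k: 2 * v for k, v in w.items()}
        assert weighted_density(region, occs, w2) == pytest.approx(
            2 * weighted_density(region, occs, w))

    def test_weights_count_training_cnvs_containing_the_duplicon(self):
        cnvs = [GenomicInterval("chr1", 0, 1000, "c1", "CNV"),
                GenomicInterval("chr1", 2000, 3000, "c2", "CNV")]
        occs = [_occ("a", "chr1", 100, 200), _occ("a", "chr1", 2100, 2200),
                _occ("b", "chr1", 500, 600)]
        assert duplicon_weights(occs, cnvs) == {"a": 2.0, "b": 1.0}


class TestIntervalOps:
    def test_merge_and_complement(self):
        cnvs = [GenomicInterval("chr1", 100, 300, "a", "CNV"),
                GenomicInterval("chr1", 250, 400, "b", "CNV"),
                GenomicInterval("chr1", 600, 700, "c", "CNV")]
        merged = merge_intervals(cnvs)
        assert [(iv.start, iv.end) for iv in merged] == [(100, 400), (600, 700)]
        comp = complement_intervals(cnvs, {"chr1": 1000})
        assert [(iv.start, iv.end) for iv in comp] == [(0, 100), (400, 600), (700, 1000)]
        assert all(iv.category == "non-CNV" for iv in comp)


class TestCompareDensities:
    def test_identical_collections_give_t_zero_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = compare_densities(vals, vals)
        assert res.t == 0.0 and res.p_value == 1.0

    def test_matches_hand_computed_welch_formula(self):
        a, b = [4.0, 6.0], [1.0, 2.0]
        # means 5, 1.5; variances 2, 0.5; se = sqrt(2/2 + 0.5/2) = sqrt(1.25)
        t = (5 - 1.5) / np.sqrt(1.25)
        df = 1.25**2 / ((1.0**2) / 1 + (0.25**2) / 1)
        res = compare_densities(a, b)
        assert res.t == pytest.approx(t)
        assert res.df == pytest.approx(df)
        assert res.mean_a == 5.0 and res.mean_b == 1.5

    def test_separated_groups_reach_genomewide_significance(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(20):
            a = rng.normal(4.3, 0.5, size=24)
            b = rng.normal(1.8, 0.5, size=24)
            if compare_densities(a, b).p_value < 1e-5:
                hits += 1
        assert hits == 20

    def test_zero_variance_distinct_means_is_undefined(self):
        with pytest.raises(ValueError):
            compare_densities([1.0, 1.0], [2.0, 2.0])
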