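"""Anchors, hypergeometric duplex-interaction test and permutation FDR."""

import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom as scipy_hypergeom

from chiapet.interactions import (
    Anchor,
    InteractionCluster,
    call_anchors,
    call_interactions,
    estimate_extension_length,
    extend_tags,
    filter_interactions,
    hypergeom_pvalue,
    pair_counts,
    permutation_fdr,
    score_pairs,
)
from tests.conftest import mk_pet


class TestExtensionLength:
    def test_small_sample_mode_bin(self):
        # fewer than 100 spans -> fallback, so replicate the values
        spans = [180, 190, 200, 200, 210] * 30
        est = estimate_extension_length(spans)
        assert 200 <= est <= 210  # the 200-containing bin's centre

    def test_empty_input_falls_back(self):
        assert estimate_extension_length([]) == 200

    def test_unimodal_simulated_mode(self):
        rng = np.random.default_rng(3)
        spans = rng.normal(250, 30, 10_000).astype(int)
        assert abs(estimate_extension_length(spans) - 250) <= 10


class TestExtendTags:
    LENGTHS = {"chr1": 100_000}

    def test_plus_strand_extends_right(self):
        pet = mk_pet(pos1=1000, pos2=50_000)
        [(a, _)] = extend_tags([pet], 200, self.LENGTHS)
        assert a == ("chr1", 1000, 1200)

    def test_minus_strand_extends_left(self):
        pet = mk_pet(pos1=50_000, pos2=1000, strand2="+", strand1="-")
        # canonical ordering puts pos 1000 first; its strand is '+'
        [(a, b)] = extend_tags([pet], 200, self.LENGTHS)
        assert b == ("chr1", 49_820, 50_020)

    def test_clipped_at_chromosome_start(self):
        pet = mk_pet(pos1=5, pos2=50_000, strand1="-")
        [(a, _)] = extend_tags([pet], 200, self.LENGTHS)
        assert a == ("chr1", 0, 25)

    def test_extension_below_tag_length_rejected(self):
        with pytest.raises(ValueError):
            extend_tags([mk_pet()], 10, self.LENGTHS)


class TestAnchors:
    def test_overlapping_stack_is_one_anchor(self):
        ivs = [("chr1", 100 + 10 * i, 400 + 10 * i) for i in range(5)]
        [a] = call_anchors(ivs)
        assert a.c == 5 and a.peak_height == 5
        assert (a.start, a.end) == (100, 440)

    def test_bridge_valley_splits_two_stacks(self):
        """Two height-4 stacks joined by a single bridging tag: coverage
        4..5..1..5..4 by construction, valley 1 < 0.5*4 -> split."""
        left = [("chr1", 0, 200)] * 4
        right = [("chr1", 600, 800)] * 4
        bridge = [("chr1", 150, 650)]
        anchors = call_anchors(left + right + bridge, valley_ratio=0.5)
        assert len(anchors) == 2
        (a, b) = anchors
        assert a.end <= 200 + 1 and b.start >= 600 - 1
        assert a.c == b.c == 5  # the bridge tag overlaps both

    def test_no_split_when_valley_is_shallow(self):
        left = [("chr1", 0, 200)] * 3
        right = [("chr1", 150, 350)] * 3
        anchors = call_anchors(left + right, valley_ratio=0.5)
        assert len(anchors) == 1 and anchors[0].c == 6

    def test_lone_tag_below_min_support(self):
        assert call_anchors([("chr1", 0, 200)], min_c=2) == []


def _mk_anchor(chrom="chr1", start=0, end=100, c=2):
    return Anchor(chrom, start, end, c, c)


class TestPairCounts:
    def test_five_pets_linking_two_anchors(self):
        anchors = [_mk_anchor(start=0, end=500, c=5), _mk_anchor(start=10_000, end=10_500, c=5)]
        pets = [(("chr1", 100, 300), ("chr1", 10_100, 10_300))] * 5
        assert pair_counts(pets, anchors) == {(0, 1): 5}

    def test_both_tags_in_one_anchor_ignored(self):
        anchors = [_mk_anchor(start=0, end=500, c=2)]
        pets = [(("chr1", 10, 210), ("chr1", 250, 450))]
        assert pair_counts(pets, anchors) == {}

    def test_tag_outside_all_anchors_contributes_nothing(self):
        anchors = [_mk_anchor(start=0, end=500, c=1)]
        pets = [(("chr1", 100, 300), ("chr1", 90_000, 90_200))]
        assert pair_counts(pets, anchors) == {}

    def test_matches_quadratic_oracle(self, rng):
        """Random PETs against a brute-force double loop over all
        (PET, anchor, anchor) combinations."""
        anchors = []
        pos = 0
        for _ in range(40):
            pos += int(rng.integers(300, 2000))
            end = pos + int(rng.integers(100, 400))
            anchors.append(_mk_anchor(start=pos, end=end, c=1))
            pos = end
        pets = []
        for _ in range(1500):
            s1 = int(rng.integers(0, pos))
            s2 = int(rng.integers(0, pos))
            pets.append((("chr1", s1, s1 + 200), ("chr1", s2, s2 + 200)))

        def overlaps(iv, a):
            return iv[1] < a.end and a.start < iv[2]

        oracle: dict[tuple[int, int], int] = {}
        for p in pets:
            linked = set()
            for i, a in enumerate(anchors):
                for j, b in enumerate(anchors):
                    if i < j and (
                        (overlaps(p[0], a) and overlaps(p[1], b))
                        or (overlaps(p[0], b) and overlaps(p[1], a))
                    ):
                        linked.add((i, j))
            for key in linked:
                oracle[key] = oracle.get(key, 0) + 1
        assert pair_counts(pets, anchors) == oracle


class TestHypergeometric:
    def test_enumeration_small_case(self):
        # N=5 PETs -> 10 ends; c_A=3, c_B=2: P(X>=1) = 1 - C(7,2)/C(10,2)
        assert hypergeom_pvalue(5, 3, 2, 1) == pytest.approx(24 / 45, abs=1e-12)

    def test_zero_links_give_p_one(self):
        assert hypergeom_pvalue(10, 4, 3, 0) == 1.0

    def test_all_ends_in_anchor_a(self):
        assert hypergeom_pvalue(5, 10, 3, 3) == pytest.approx(1.0)

    def test_exhaustive_enumeration_all_small_grids(self):
        """Upper tail equals direct enumeration of the hypergeometric pmf
        for every (2N <= 20, c_A, c_B, I) combination."""
        from math import comb

        for two_n in range(2, 21, 2):
            n = two_n // 2
            for c_a in range(1, two_n + 1):
                for c_b in range(1, two_n + 1):
                    if max(0, c_b - (two_n - c_a)) > min(c_a, c_b):
                        continue
                    total = comb(two_n, c_b)
                    for i_ab in range(0, min(c_a, c_b) + 1):
                        brute = sum(
                            comb(c_a, i) * comb(two_n - c_a, c_b - i)
                            for i in range(i_ab, min(c_a, c_b) + 1)
                        ) / total
                        assert hypergeom_pvalue(n, c_a, c_b, i_ab) == pytest.approx(
                            brute, abs=1e-10
                        )

    def test_agrees_with_scipy_cross_check(self):
        for n, c_a, c_b, i in [(100, 30, 20, 5), (500, 80, 60, 12), (1000, 10, 10, 3)]:
            expect = scipy_hypergeom.sf(i - 1, 2 * n, c_a, c_b)
            assert hypergeom_pvalue(n, c_a, c_b, i) == pytest.approx(expect, rel=1e-9)

    def test_monotone_in_link_count(self):
        ps = [hypergeom_pvalue(200, 30, 25, i) for i in range(0, 26)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_enrichment_bias_penalised(self):
        """At fixed I_AB, higher anchor enrichment c_A*c_B raises the
        p-value (more links expected by chance)."""
        low = hypergeom_pvalue(500, 10, 10, 4)
        high = hypergeom_pvalue(500, 40, 40, 4)
        assert high > low

    def test_forced_support_is_certain(self):
        # 2N = c_A = c_B = 4: every draw lands in A, so X = 4 always
        assert hypergeom_pvalue(2, 4, 4, 4) == pytest.approx(1.0)

    def test_counts_beyond_pool_raise(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(3, 7, 2, 1)


def _toy_interaction(p=0.001, i_ab=5, fdr=0.0, chrom_b="chr1"):
    a = _mk_anchor(start=0, end=100, c=10)
    b = _mk_anchor(chrom=chrom_b, start=10_000, end=10_100, c=10)
    return InteractionCluster(a, b, i_ab, p, fdr)


class TestPermutationFdrAndCalling:
    def build_looped_dataset(self, rng, n_loops=4, depth=8, n_background=400):
        genome_bp = 5_000_000
        pets = []
        loop_pos = [(int(p), int(p) + 500_000) for p in rng.integers(0, 4_000_000, n_loops)]
        for pa, pb in loop_pos:
            for _ in range(depth):
                s1 = pa + int(rng.integers(0, 150))
                s2 = pb + int(rng.integers(0, 150))
                pets.append((("chr1", s1, s1 + 200), ("chr1", s2, s2 + 200)))
        for _ in range(n_background):
            s1 = int(rng.integers(0, genome_bp))
            s2 = int(rng.integers(0, genome_bp))
            pets.append((("chr1", s1, s1 + 200), ("chr1", s2, s2 + 200)))
        return pets, loop_pos

    def test_deterministic_given_seed(self, rng):
        pets, _ = self.build_looped_dataset(rng)
        anchors = call_anchors([iv for p in pets for iv in p])
        clusters = score_pairs(pair_counts(pets, anchors), anchors, len(pets))
        f1 = permutation_fdr(clusters, pets, anchors, n_perm=3, seed=11)
        f2 = permutation_fdr(clusters, pets, anchors, n_perm=3, seed=11)
        assert f1 == f2

    def test_planted_loops_significant_background_not(self, rng):
        pets, loop_pos = self.build_looped_dataset(rng)
        anchors = call_anchors([iv for p in pets for iv in p])
        clusters = score_pairs(pair_counts(pets, anchors), anchors, len(pets))
        fdrs = permutation_fdr(clusters, pets, anchors, n_perm=5, seed=1)
        for c, f in zip(clusters, fdrs):
            c.fdr = f
        intra, inter = call_interactions(clusters, min_pets=3, fdr_max=0.05)
        assert not inter
        called_midpoints = [
            ((c.anchor_a.start + c.anchor_a.end) // 2, (c.anchor_b.start + c.anchor_b.end) // 2)
            for c in intra
        ]
        for pa, pb in loop_pos:
            assert any(
                abs(ma - pa) < 500 and abs(mb - pb) < 500 for ma, mb in called_midpoints
            )

    def test_fully_random_pets_rarely_called(self, rng):
        """End-permuted (null) data: the hypergeometric + permutation-FDR
        pipeline calls essentially nothing."""
        pets, _ = self.build_looped_dataset(rng, n_loops=0, n_background=600)
        anchors = call_anchors([iv for p in pets for iv in p])
        clusters = score_pairs(pair_counts(pets, anchors), anchors, len(pets))
        fdrs = permutation_fdr(clusters, pets, anchors, n_perm=5, seed=3)
        for c, f in zip(clusters, fdrs):
            c.fdr = f
        intra, inter = call_interactions(clusters, min_pets=3, fdr_max=0.05)
        assert len(intra) + len(inter) == 0

    def test_min_pets_dominates_p_value(self):
        weak = _toy_interaction(p=1e-12, i_ab=2, fdr=0.0)
        strong = _toy_interaction(p=0.001, i_ab=5, fdr=0.01)
        intra, _ = call_interactions([weak, strong])
        assert intra == [strong]


class TestInteractionFilters:
    def test_mitochondrial_anchor_removed(self):
        ints = [_toy_interaction(chrom_b="chrM"), _toy_interaction()]
        kept = filter_interactions(ints)
        assert len(kept) == 1 and kept[0].anchor_b.chrom == "chr1"

    def test_sv_breakpoint_window(self):
        ints = [_toy_interaction()]
        kept = filter_interactions(ints, sv_breakpoints=[("chr1", 12_000, 12_001)])
        assert kept == []  # anchor B at 10,000-10,100 is within 10 kb
        kept = filter_interactions(
            ints, sv_breakpoints=[("chr1", 12_000, 12_001)], sv_window_bp=1000
        )
        assert len(kept) == 1

    def test_blacklist_overlap(self):
        ints = [_toy_interaction()]
        assert filter_interactions(ints, blacklist=[("chr1", 50, 60)]) == []

    def test_defaults_only_drop_chry_chrm(self):
        ints = [_toy_interaction(), _toy_interaction(chrom_b="chrY")]
        assert len(filter_interactions(ints)) == 1
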