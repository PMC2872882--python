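"""Deduplication, span model, PET categories and random-ligation stats."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chiapet.classify import (
    PETCategory,
    SpanFitConfig,
    SpanFitError,
    binomial_rate_test,
    categorize,
    classify_pet,
    dedupe_pets,
    density_matrix,
    expected_intra_rate,
    fit_or_default_cutoff,
    fit_span_model,
    genomic_span,
    observed_intra_rate,
)
from chiapet.simulate import sample_spans
from tests.conftest import mk_pet


class TestDedupe:
    def test_within_one_bp_merges(self):
        pets = [mk_pet("a", pos1=100, pos2=600), mk_pet("b", pos1=101, pos2=601)]
        unique, dups = dedupe_pets(pets)
        assert len(unique) == 1 and dups == 1
        assert unique[0].head.pos == 100  # smallest-coordinate representative

    def test_three_bp_apart_stays(self):
        pets = [mk_pet("a", pos1=100, pos2=600), mk_pet("b", pos1=103, pos2=600)]
        unique, dups = dedupe_pets(pets)
        assert len(unique) == 2 and dups == 0

    def test_strands_must_match(self):
        pets = [
            mk_pet("a", pos1=100, pos2=600, strand2="-"),
            mk_pet("b", pos1=100, pos2=600, strand2="+"),
        ]
        unique, _ = dedupe_pets(pets)
        assert len(unique) == 2

    def test_poisson_duplication_recovers_loci(self, rng):
        """100 distinct loci sampled with Poisson duplication collapse back
        to exactly 100 unique PETs."""
        loci = [
            (int(p1), int(p2))
            for p1, p2 in zip(
                rng.choice(10**6, 100, replace=False) * 10,
                rng.choice(10**6, 100, replace=False) * 10,
            )
        ]
        pets = []
        i = 0
        for p1, p2 in loci:
            for _ in range(1 + rng.poisson(4)):
                jitter1, jitter2 = int(rng.integers(0, 2)), int(rng.integers(0, 2))
                pets.append(mk_pet(f"p{i}", pos1=p1 + jitter1, pos2=p2 + jitter2))
                i += 1
        unique, dups = dedupe_pets(pets)
        assert len(unique) == 100
        assert dups == len(pets) - 100

    def test_idempotence(self, rng):
        pets = [
            mk_pet(f"p{i}", pos1=int(rng.integers(0, 3000)), pos2=int(rng.integers(0, 3000)))
            for i in range(300)
        ]
        once, _ = dedupe_pets(pets)
        twice, dups = dedupe_pets(once)
        assert [p.id for p in twice] == [p.id for p in once]
        assert dups == 0


class TestSpanAndCategories:
    def test_span_head_to_tail(self):
        assert genomic_span(mk_pet(pos1=100, pos2=1480)) == 1400

    def test_span_interchromosomal_undefined(self):
        assert genomic_span(mk_pet(chrom2="chr2")) is None

    def test_span_degenerate_identical_tags(self):
        assert genomic_span(mk_pet(pos1=100, pos2=100, strand2="+")) == 20

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(pos1=100, pos2=1480), PETCategory.SELF_LIGATION),
            (dict(pos1=100, pos2=1480, strand2="+"), PETCategory.DIFFERENT_ORIENTATION),
            (dict(pos1=100, pos2=1480, strand1="-", strand2="-"), PETCategory.DIFFERENT_ORIENTATION),
            (dict(chrom2="chr5"), PETCategory.INTER_CHROM),
            (dict(pos1=100, pos2=50_080), PETCategory.INTRA_INTER),
        ],
    )
    def test_category_rules(self, kwargs, expected):
        assert classify_pet(mk_pet(**kwargs), cutoff_bp=4595) is expected

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            classify_pet(mk_pet(), cutoff_bp=0)

    def test_partition_and_cutoff_monotonicity(self, rng):
        pets = []
        for i in range(500):
            same = rng.random() < 0.7
            pets.append(
                mk_pet(
                    f"p{i}",
                    pos1=int(rng.integers(0, 10**6)),
                    pos2=int(rng.integers(0, 10**6)),
                    chrom2="chr1" if same else "chr9",
                    strand1="+-"[rng.integers(0, 2)],
                    strand2="+-"[rng.integers(0, 2)],
                )
            )
        lo = categorize(pets, 2000)
        hi = categorize(pets, 20_000)
        for cats in (lo, hi):
            assert sum(len(v) for v in cats.values()) == len(pets)
        short_lo = len(lo[PETCategory.SELF_LIGATION]) + len(lo[PETCategory.DIFFERENT_ORIENTATION])
        short_hi = len(hi[PETCategory.SELF_LIGATION]) + len(hi[PETCategory.DIFFERENT_ORIENTATION])
        assert short_hi >= short_lo


class TestSpanModel:
    def test_recovers_planted_mixture(self):
        """Two-power-law mixture: fitted slopes within +/-0.15 of the
        generating exponents, cutoff within +/-20% of the analytic
        intersection of the generating lines."""
        rng = np.random.default_rng(42)
        n = 50_000
        spans = np.concatenate(
            [
                sample_spans(2.5, (200, 3000), int(0.6 * n), rng),
                sample_spans(1.2, (3000, 1_000_000), n - int(0.6 * n), rng),
            ]
        )
        model = fit_span_model(spans)

        def line(a, lo, hi, w):
            norm = (a - 1) / (lo ** (1 - a) - hi ** (1 - a))
            return np.log10(w * norm), -a

        i1, s1 = line(2.5, 200, 3000, 0.6)
        i2, s2 = line(1.2, 3000, 1_000_000, 0.4)
        analytic = 10 ** ((i2 - i1) / (s1 - s2))
        assert abs(model.slope_left - (-2.5)) < 0.15
        assert abs(model.slope_right - (-1.2)) < 0.15
        assert abs(model.cutoff_bp - analytic) / analytic < 0.20
        assert model.slope_left < model.slope_right < 0

    def test_single_power_law_rejected(self):
        rng = np.random.default_rng(7)
        spans = sample_spans(2.0, (200, 200_000), 30_000, rng)
        with pytest.raises(SpanFitError):
            fit_span_model(spans)

    def test_too_few_spans_advises_manual_cutoff(self):
        with pytest.raises(SpanFitError, match="manual"):
            fit_span_model([100, 200, 300])

    def test_fallback_default(self):
        cutoff, model = fit_or_default_cutoff([500] * 2000, default_cutoff=5000)
        assert cutoff == 5000 and model is None


class TestRandomLigationModel:
    def test_single_chromosome_rate_is_one(self):
        assert expected_intra_rate({"chr1": 7}) == 1.0

    def test_two_equal_chromosomes(self):
        assert expected_intra_rate([5, 5]) == 0.5

    def test_three_one_split(self):
        assert expected_intra_rate([3, 1]) == 0.625

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            expected_intra_rate([0, 0])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=6).filter(
            lambda c: 0 < sum(c) <= 50
        )
    )
    def test_matches_exhaustive_pair_enumeration(self, counts):
        """sum(n^2)/N^2 equals brute-force enumeration of ordered fragment
        pairs (with replacement) for any counts with N <= 50."""
        labels = [i for i, c in enumerate(counts) for _ in range(c)]
        pairs = list(itertools.product(labels, repeat=2))
        brute = sum(a == b for a, b in pairs) / len(pairs)
        assert expected_intra_rate(counts) == pytest.approx(brute, abs=1e-12)

    def test_without_replacement_variant(self):
        # 2 chroms x 2 frags: ordered distinct pairs 4*3=12, intra 2+2=4
        assert expected_intra_rate([2, 2], with_replacement=False) == pytest.approx(4 / 12)

    def test_observed_rates_from_printed_counts(self):
        assert round(observed_intra_rate(91_519, 893_213), 4) == 0.0929
        assert round(observed_intra_rate(94_743, 1_602_889), 4) == 0.0558

    def test_observed_rate_zero_intra(self):
        assert observed_intra_rate(0, 10) == 0.0

    def test_observed_rate_empty_raises(self):
        with pytest.raises(ValueError):
            observed_intra_rate(0, 0)


class TestBinomialRateTest:
    def test_observed_at_mode_gives_one(self):
        assert binomial_rate_test(5, 100, 0.05).pvalue == pytest.approx(1.0)
        assert binomial_rate_test(10, 20, 0.5).pvalue == pytest.approx(1.0)

    def test_p0_bounds(self):
        for p0 in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                binomial_rate_test(1, 10, p0)

    def test_successes_cannot_exceed_trials(self):
        with pytest.raises(ValueError):
            binomial_rate_test(11, 10, 0.5)

    def test_normal_approximation_tracks_exact(self):
        exact = binomial_rate_test(560, 10_000, 0.05, method="exact")
        approx = binomial_rate_test(560, 10_000, 0.05, method="normal_approx")
        assert approx.method == "normal_approx"
        assert approx.pvalue == pytest.approx(exact.pvalue, rel=0.15)


class TestDensityMatrix:
    LENGTHS = {"chr1": 1000, "chr2": 1000}

    def test_single_pair_dominates(self):
        pets = [mk_pet(f"p{i}", chrom1="chr1", chrom2="chr2") for i in range(5)]
        mat = density_matrix(pets, self.LENGTHS)
        assert mat.loc["chr1", "chr2"] == 1.0
        assert mat.loc["chr2", "chr1"] == 1.0
        assert mat.loc["chr1", "chr1"] == 0.0

    def test_empty_input_zero_matrix(self):
        mat = density_matrix([], self.LENGTHS)
        assert (mat.values == 0).all()

    def test_uniform_pairs_balanced(self, rng):
        """Uniform random tag pairs over two equal chromosomes fill the four
        squares evenly (within 3 binomial sigma of the expected count)."""
        n = 4000
        pets = []
        for i in range(n):
            c1, c2 = rng.choice(["chr1", "chr2"], 2)
            pets.append(mk_pet(f"p{i}", chrom1=c1, chrom2=c2))
        mat = density_matrix(pets, self.LENGTHS, length_normalize=False)
        counts = np.zeros((2, 2))
        for p in pets:
            i, j = ("chr1", "chr2").index(p.head.chrom), ("chr1", "chr2").index(p.tail.chrom)
            counts[i, j] += 1
            if i != j:
                counts[j, i] += 1
        # each diagonal cell ~ Binomial(n, 1/4); the symmetrised off-diagonal
        # cell collects both ordered combinations ~ Binomial(n, 1/2)
        sigma_diag = np.sqrt(n * 0.25 * 0.75)
        sigma_off = np.sqrt(n * 0.5 * 0.5)
        assert abs(counts[0, 0] - n / 4) < 3 * sigma_diag
        assert abs(counts[1, 1] - n / 4) < 3 * sigma_diag
        assert abs(counts[0, 1] - n / 2) < 3 * sigma_off
        assert mat.values.max() == 1.0
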