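"""Binary patterns, the Hamming metric, and controlled-distance pair generation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ca1sep.patterns import (
    BinaryPattern,
    PatternPair,
    distinct_hd,
    hamming,
    max_hd,
    pair_with_hd,
    random_pattern,
    read_patterns,
    similar_hd,
    write_patterns,
)


def bp(length, idx):
    return BinaryPattern.from_indices(length, idx)


V0 = bp(5, [])
V1 = bp(5, [1, 3, 4])
V2 = bp(5, [1, 2, 3])


class TestHamming:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(V0, V1, 3), (V1, V2, 2), (V1, V1, 0), (V0, V0, 0)],
    )
    def test_worked_examples(self, a, b, expected):
        assert hamming(a, b) == expected
        assert hamming(b, a) == expected

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            hamming(bp(5, [1]), bp(6, [1]))

    @given(
        st.integers(2, 40).flatmap(
            lambda n: st.tuples(
                st.just(n),
                *[st.sets(st.integers(0, n - 1)) for _ in range(3)],
            )
        )
    )
    def test_is_a_metric(self, args):
        n, sa, sb, sc = args
        a, b, c = bp(n, sa), bp(n, sb), bp(n, sc)
        assert hamming(a, b) == hamming(b, a)
        assert (hamming(a, b) == 0) == (a.active == b.active)
        assert hamming(a, c) <= hamming(a, b) + hamming(b, c)


class TestMaxHd:
    @pytest.mark.parametrize(
        "length, k, expected",
        [(28009, 1540, 3080), (45073, 3086, 6172), (3, 2, 2), (10, 0, 0)],
    )
    def test_values(self, length, k, expected):
        assert max_hd(length, k) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            max_hd(5, 6)


class TestTargetHds:
    @pytest.mark.parametrize(
        "length, k, expected",
        [(28009, 1540, 62), (45073, 3086, 124)],
    )
    def test_similar_two_percent(self, length, k, expected):
        assert similar_hd(length, k) == expected

    def test_similar_full_fraction_is_max(self):
        assert similar_hd(100, 20, 1.0) == max_hd(100, 20)

    def test_similar_bad_fraction(self):
        with pytest.raises(ValueError):
            similar_hd(100, 20, 0.0)

    @pytest.mark.parametrize(
        "length, k, expected",
        [(28009, 1540, 2910), (45073, 3086, 5750)],
    )
    def test_distinct_is_binomial_mean(self, length, k, expected):
        assert distinct_hd(length, k) == expected

    def test_distinct_small_case_against_enumeration(self):
        # brute-force mean HD over all equal-count partners of a fixed pattern
        # (uniform over pairs by symmetry) vs the binomial approximation
        n, k = 6, 3
        a = frozenset(range(k))
        hds = [
            len(a ^ frozenset(c)) for c in itertools.combinations(range(n), k)
        ]
        brute_mean = np.mean(hds)
        binom_mean = n * 2 * (k / n) * (1 - k / n)
        assert abs(brute_mean - binom_mean) < 1

    def test_target_hds_are_even(self):
        for length, k in [(101, 7), (500, 33), (1000, 69), (28009, 1540)]:
            assert similar_hd(length, k) % 2 == 0
            assert distinct_hd(length, k) % 2 == 0


class TestRandomPattern:
    def test_exact_count_and_bounds(self):
        rng = np.random.default_rng(0)
        p = random_pattern(200, 30, rng)
        assert p.k == 30
        assert all(0 <= i < 200 for i in p.active)

    @pytest.mark.parametrize("k", [0, 10])
    def test_degenerate_counts(self, k):
        p = random_pattern(10, k, np.random.default_rng(0))
        assert p.k == k

    def test_reproducible(self):
        p1 = random_pattern(500, 40, np.random.default_rng(42))
        p2 = random_pattern(500, 40, np.random.default_rng(42))
        assert p1 == p2

    def test_uniform_inclusion_frequency(self):
        # per-index inclusion frequency over 10^4 draws within 4 binomial SDs
        n, k, draws = 200, 30, 10_000
        rng = np.random.default_rng(7)
        counts = np.zeros(n)
        for _ in range(draws):
            counts[random_pattern(n, k, rng).indices()] += 1
        p = k / n
        band = 4 * np.sqrt(p * (1 - p) / draws)
        freqs = counts / draws
        assert np.all(np.abs(freqs - p) < band)


class TestPairWithHd:
    @given(
        st.integers(2, 60).flatmap(
            lambda n: st.tuples(st.just(n), st.integers(0, n)).flatmap(
                lambda nk: st.tuples(
                    st.just(nk[0]),
                    st.just(nk[1]),
                    st.integers(0, min(max_hd(*nk) // 2, nk[0] - nk[1])).map(lambda h: 2 * h),
                    st.integers(0, 2**31 - 1),
                )
            )
        )
    )
    def test_realized_equals_target(self, args):
        n, k, d, seed = args
        pair = pair_with_hd(n, k, d, np.random.default_rng(seed))
        assert hamming(pair.a, pair.b) == d
        assert pair.a.k == pair.b.k == k

    def test_zero_distance_identical(self):
        pair = pair_with_hd(50, 10, 0, np.random.default_rng(0))
        assert pair.a == pair.b

    def test_paper_scale_similar_pair(self):
        pair = pair_with_hd(28009, 1540, 62, np.random.default_rng(3))
        assert hamming(pair.a, pair.b) == 62
        assert pair.a.k == pair.b.k == 1540

    def test_odd_distance_rejected(self):
        with pytest.raises(ValueError, match="even"):
            pair_with_hd(50, 10, 3, np.random.default_rng(0))

    def test_infeasible_distance_rejected(self):
        with pytest.raises(ValueError):
            pair_with_hd(10, 5, 12, np.random.default_rng(0))

    def test_pair_invariant_enforced(self):
        with pytest.raises(ValueError, match="realized"):
            PatternPair(a=bp(5, [0]), b=bp(5, [1]), target_hd=4)


class TestSerialization:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        pats = [random_pattern(120, k, rng) for k in (0, 1, 17, 120)]
        path = tmp_path / "pats.txt"
        write_patterns(path, pats)
        assert read_patterns(path) == pats
        # deterministic serialization: identical bytes on rewrite
        path2 = tmp_path / "pats2.txt"
        write_patterns(path2, pats)
        assert path.read_bytes() == path2.read_bytes()

    def test_mixed_lengths_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="mixed"):
            write_patterns(tmp_path / "x.txt", [bp(5, [0]), bp(6, [0])])
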