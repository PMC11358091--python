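import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecognet.complexity import (
    EmbeddingParams,
    complexity_table,
    embed,
    lz_phrase_count,
    ordinal_index,
    permutation_entropy,
    plzc,
    symbolize,
)
from ecognet.synth import gen_known_series


# ---------------------------------------------------------------- oracles
def brute_force_pe(series, m, tau):
    """Independent oracle: count ordinal patterns via explicit sorting."""
    series = np.asarray(series, float)
    counts = {}
    for i in range(len(series) - (m - 1) * tau):
        window = tuple(series[i + j * tau] for j in range(m))
        pattern = tuple(sorted(range(m), key=lambda k: (window[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    ps = [c / total for c in counts.values()]
    if len(ps) == 1:
        return 0.0
    h = -sum(p * math.log(p) for p in ps)
    return h / math.log(math.factorial(m))


def naive_lz_parser(symbols):
    """Independent oracle: the S/Q phrase parser with explicit list scans."""
    s = [int(v) for v in symbols]
    n = len(s)

    def contains(haystack, needle):
        for start in range(len(haystack) - len(needle) + 1):
            if haystack[start:start + len(needle)] == needle:
                return True
        return False

    c = 1
    q_start, q_end = 1, 2
    while q_end <= n:
        if contains(s[: q_end - 1], s[q_start:q_end]):
            q_end += 1
        else:
            c += 1
            q_start = q_end
            q_end += 1
    if q_start < n:
        c += 1
    return c


# ---------------------------------------------------------------- embedding
class TestEmbed:
    def test_m2_tau1(self):
        vecs = embed([1, 2, 3, 4], EmbeddingParams(m=2, tau=1))
        np.testing.assert_array_equal(vecs, [[1, 2], [2, 3], [3, 4]])

    def test_boundary_single_vector(self):
        vecs = embed([1, 2, 3, 4, 5], EmbeddingParams(m=3, tau=2))
        np.testing.assert_array_equal(vecs, [[1, 3, 5]])

    def test_count_formula(self, rng):
        vecs = embed(rng.standard_normal(1000), EmbeddingParams(m=4, tau=1))
        assert len(vecs) == 997

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            embed([1, 2], EmbeddingParams(m=3, tau=2))


class TestOrdinalIndex:
    def test_m2_patterns_distinct(self):
        assert ordinal_index([1, 2]) != ordinal_index([2, 1])

    @pytest.mark.parametrize("m", [3, 4])
    def test_bijective_over_permutations(self, m):
        indices = {
            ordinal_index(perm) for perm in itertools.permutations(range(m))
        }
        assert indices == set(range(math.factorial(m)))

    def test_ties_broken_by_position(self):
        # equal values rank earlier-position-first: (5, 5) is "ascending"
        assert ordinal_index([5, 5]) == ordinal_index([1, 2])


class TestSymbolize:
    def test_constant_series_single_symbol(self):
        seq = symbolize(np.ones(50), EmbeddingParams(m=2, tau=1))
        assert len(set(seq.symbols.tolist())) == 1

    def test_monotonic_single_symbol(self):
        seq = symbolize(np.arange(200.0), EmbeddingParams(m=3, tau=1))
        assert len(set(seq.symbols.tolist())) == 1

    def test_alternating_two_symbols(self):
        x = np.tile([1.0, 2.0], 20)
        seq = symbolize(x, EmbeddingParams(m=2, tau=1))
        assert len(set(seq.symbols.tolist())) == 2
        assert (seq.symbols[::2] == seq.symbols[0]).all()

    def test_matches_scalar_ordinal_index(self, rng):
        x = rng.standard_normal(300)
        p = EmbeddingParams(m=4, tau=2)
        seq = symbolize(x, p)
        expected = [ordinal_index(v) for v in embed(x, p)]
        np.testing.assert_array_equal(seq.symbols, expected)


class TestPermutationEntropy:
    def test_monotone_series_zero(self):
        for m in (2, 3, 4):
            assert permutation_entropy(np.arange(500.0), EmbeddingParams(m, 1)) == 0.0

    def test_worked_example(self):
        # [4,7,9,10,6,11,3], m=2: 4 ascents, 2 descents ->
        # -(2/3)ln(2/3)-(1/3)ln(1/3) / ln 2 = 0.9183
        pe = permutation_entropy([4, 7, 9, 10, 6, 11, 3], EmbeddingParams(2, 1))
        assert pe == pytest.approx(0.9183, abs=1e-4)

    def test_iid_near_one(self):
        s = gen_known_series("iid_uniform", 100_000, seed=1)
        assert permutation_entropy(s, EmbeddingParams(3, 1)) >= 0.99

    @pytest.mark.parametrize("m,tau", [(2, 1), (3, 1), (3, 2), (4, 1)])
    def test_matches_brute_force(self, rng, m, tau):
        x = rng.standard_normal(400)
        assert permutation_entropy(x, EmbeddingParams(m, tau)) == pytest.approx(
            brute_force_pe(x, m, tau), abs=1e-12
        )

    def test_bounds_and_monotone_invariance(self, rng):
        # ordinal statistics are invariant under strictly monotone transforms
        x = rng.standard_normal(1000)
        p = EmbeddingParams(3, 1)
        base = permutation_entropy(x, p)
        assert 0.0 <= base <= 1.0
        assert permutation_entropy(x**3, p) == pytest.approx(base, abs=1e-12)
        assert permutation_entropy(np.exp(x), p) == pytest.approx(base, abs=1e-12)


class TestLZPhraseCount:
    def test_constant_sequence_two_phrases(self):
        for n in (2, 5, 50, 500):
            assert lz_phrase_count(np.zeros(n, dtype=int)) == 2

    def test_alternating_matches_reference(self):
        sym = np.tile([0, 1], 6)
        assert lz_phrase_count(sym) == naive_lz_parser(sym)

    def test_matches_naive_reference_extensively(self, rng):
        for _ in range(200):
            alphabet = int(rng.choice([2, 6, 24]))
            n = int(rng.integers(10, 501))
            sym = rng.integers(0, alphabet, n)
            assert lz_phrase_count(sym) == naive_lz_parser(sym)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lz_phrase_count([1])


class TestPLZC:
    def test_constant_closed_form(self):
        # c = 2 for a constant symbol sequence of any length
        x = np.ones(1000)
        p = EmbeddingParams(m=3, tau=1)
        n = 1000 - 2
        expected = 2 * (math.log(n) / math.log(6) + 1) / n
        assert plzc(x, p) == pytest.approx(expected, rel=1e-12)

    def test_iid_level(self):
        # Monte-Carlo oracle over seeds gives 0.742 +/- 0.005 at m=3, n=1e4
        vals = [
            plzc(gen_known_series("iid_uniform", 10_000, seed=s), EmbeddingParams(3, 1))
            for s in range(5)
        ]
        assert 0.70 < np.mean(vals) < 0.79

    def test_deterministic(self, rng):
        x = rng.standard_normal(2000)
        assert plzc(x) == plzc(x)

    def test_periodic_below_random(self):
        p = EmbeddingParams(3, 1)
        periodic = plzc(gen_known_series("periodic", 5000), p)
        random = plzc(gen_known_series("iid_uniform", 5000, seed=0), p)
        assert periodic < random


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    x=arrays(np.float64, st.integers(10, 120),
             elements=st.floats(-1e6, 1e6, allow_nan=False,
                                allow_subnormal=False)),
    m=st.integers(2, 3),
)
def test_pe_properties_hold_for_arbitrary_series(x, m):
    """PE stays in [0, 1], matches the brute-force oracle, and is invariant
    under exact order-preserving rescaling, for arbitrary inputs including
    ties."""
    import warnings

    params = EmbeddingParams(m=m, tau=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pe = permutation_entropy(x, params)
        # scaling by a power of two is exact in binary floating point,
        # hence truly order- and tie-preserving
        pe_scaled = permutation_entropy(0.5 * x, params)
    assert 0.0 <= pe <= 1.0
    assert pe == pytest.approx(brute_force_pe(x, m, 1), abs=1e-12)
    assert pe_scaled == pytest.approx(pe, abs=1e-12)


def test_undersampling_warning(rng):
    with pytest.warns(UserWarning, match="undersampled"):
        permutation_entropy(rng.standard_normal(50), EmbeddingParams(4, 1))


class TestComplexityTable:
    def test_one_row_per_channel(self, processed_epochs, layout):
        table = complexity_table(processed_epochs[:1], layout)
        assert len(table) == 10
        assert set(table["region"]) == {"F", "P", "O"}
        assert table["pe"].between(0, 1).all()
        assert (table["plzc"] > 0).all()

    def test_region_rollup_is_arithmetic_mean(self, processed_epochs, layout):
        from ecognet.complexity import region_means

        table = complexity_table(processed_epochs[:1], layout)
        rolled = region_means(table)
        f_rows = table[table["region"] == "F"]
        f_mean = rolled[rolled["region"] == "F"]["pe"].iloc[0]
        assert f_mean == pytest.approx(f_rows["pe"].mean())

    def test_scz_more_complex_than_normal(self, tiny_cohort_processed, layout):
        vals = {}
        for cond in ("normal", "scz"):
            recs = [
                r for (s, c), rr in tiny_cohort_processed.items()
                if c == cond for r in rr
            ]
            t = complexity_table(recs, layout)
            vals[cond] = (t["pe"].mean(), t["plzc"].mean())
        assert vals["scz"][0] > vals["normal"][0]
        assert vals["scz"][1] > vals["normal"][1]
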