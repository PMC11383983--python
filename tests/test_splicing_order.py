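"""Splicing-order scores: worked examples, coverage-filter boundaries, and
equivalence with an independent brute-force path-enumeration oracle."""

import itertools

import numpy as np
import pytest

from splicord.simulate import implied_level_frequencies, implied_score_vector
from splicord.splicing_order import (
    IntronGroup,
    LevelCounts,
    canonical_orders,
    order_scores,
    pair_order_frequency,
    passes_pair_filters,
    passes_triple_filters,
    patterns_at_level,
    scores_from_frequencies,
)


def level_counts(k, counts_by_level, undetermined=None, allele="hap1"):
    return LevelCounts(
        "g:0-1-2", allele, k,
        {L: dict(c) for L, c in counts_by_level.items()},
        undetermined or {},
    )


# ---------------------------------------------------------------------------
# independent oracle: enumerate every removal order as an explicit chain of
# excised-subsets and multiply frequencies computed directly from the counts
# ---------------------------------------------------------------------------

def oracle_scores(k, counts_by_level):
    totals = {L: sum(counts_by_level.get(L, {}).values()) for L in range(1, k)}
    raws = []
    for order in sorted(itertools.permutations(range(k))):
        raw = 1.0
        for L in range(1, k):
            subset = frozenset(order[:L])
            mask = sum(1 << i for i in subset)
            c = counts_by_level.get(L, {}).get(mask, 0)
            raw *= (c / totals[L]) if totals[L] else 0.0
        raws.append(raw)
    total = sum(raws)
    return [r / total for r in raws] if total else None


def test_degenerate_single_path():
    lc = level_counts(3, {1: {0b001: 10}, 2: {0b011: 10}})
    vec = order_scores(lc)
    assert vec.scorable
    assert vec.as_dict()["1->2->3"] == 1.0
    assert sum(vec.scores) == 1.0


def test_uniform_counts_give_uniform_scores():
    lc = level_counts(3, {
        1: {p: 10 for p in patterns_at_level(3, 1)},
        2: {p: 10 for p in patterns_at_level(3, 2)},
    })
    vec = order_scores(lc)
    assert vec.scores == pytest.approx((1 / 6,) * 6)


def test_worked_example_normalization():
    """Hand-computed: L1 {1}:30 {2}:10, L2 {1,2}:20 {1,3}:20 ->
    raw (0.375, 0.375, 0.125, 0, 0, 0), normalized (3/7, 3/7, 1/7, 0, 0, 0)."""
    lc = level_counts(3, {
        1: {0b001: 30, 0b010: 10},
        2: {0b011: 20, 0b101: 20},
    })
    vec = order_scores(lc)
    assert vec.raw == pytest.approx((0.375, 0.375, 0.125, 0.0, 0.0, 0.0))
    assert vec.scores == pytest.approx((3 / 7, 3 / 7, 1 / 7, 0.0, 0.0, 0.0))
    assert vec.scores == pytest.approx(oracle_scores(3, lc.counts))


def test_all_zero_levels_are_unscorable():
    lc = level_counts(3, {1: {0b001: 10}, 2: {}})
    vec = order_scores(lc)
    assert not vec.scorable
    assert all(s == 0.0 for s in vec.scores)


@pytest.mark.parametrize("k", [2, 3])
def test_matches_bruteforce_oracle_on_random_tables(k):
    rng = np.random.default_rng(17)
    for _ in range(300):
        counts = {
            L: {p: int(rng.integers(0, 12)) for p in patterns_at_level(k, L)}
            for L in range(1, k)
        }
        lc = level_counts(k, counts)
        vec = order_scores(lc)
        expected = oracle_scores(k, counts)
        if expected is None:
            assert not vec.scorable
        else:
            assert vec.scorable
            assert vec.scores == pytest.approx(expected)
            assert sum(vec.scores) == pytest.approx(1.0, abs=1e-12)


def test_scores_invariant_to_level_rescaling():
    base = {1: {0b001: 3, 0b010: 5, 0b100: 2}, 2: {0b011: 4, 0b110: 6}}
    scaled = {1: {p: 7 * c for p, c in base[1].items()}, 2: base[2]}
    assert order_scores(level_counts(3, base)).scores == pytest.approx(
        order_scores(level_counts(3, scaled)).scores
    )


def test_implied_vector_of_degenerate_mixture_is_indicator():
    vec = implied_score_vector({(2, 0, 1): 1.0}, 3)
    expected = [1.0 if o == (2, 0, 1) else 0.0 for o in canonical_orders(3)]
    assert list(vec.scores) == expected


def test_implied_frequencies_sum_to_one_per_level():
    mix = {(0, 1, 2): 0.5, (2, 1, 0): 0.3, (1, 0, 2): 0.2}
    freqs = implied_level_frequencies(mix, 3)
    for L in range(4):
        assert sum(freqs[L].values()) == pytest.approx(1.0)


def test_score_functional_recovery_from_implied_frequencies():
    """The scorer applied to mixture-implied frequencies can spread mass to
    orders outside the mixture support (the functional, not the weights)."""
    mix = {(0, 1, 2): 0.5, (1, 2, 0): 0.5}
    vec = scores_from_frequencies(implied_level_frequencies(mix, 3), 3)
    d = vec.as_dict()
    # path products: f({1})*f({1,2}) = .25, f({2})*f({1,2}) = .25, plus
    # crossover orders 2->1->3 (f({2})*f({1,2}) = 0.25) etc.
    assert sum(vec.scores) == pytest.approx(1.0)
    assert d["1->2->3"] > 0 and d["2->3->1"] > 0


# ---------------------------------------------------------------------------
# coverage filters
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n1, n2, undet, expected",
    [
        (11, 11, 5, True),
        (10, 11, 0, False),   # strictly more than 10 per allele
        (30, 30, 15, False),  # not > 2 x undetermined
        (31, 31, 15, True),
    ],
)
def test_pair_filters(n1, n2, undet, expected):
    assert passes_pair_filters(n1, n2, undet) is expected


def make_triple_inputs(level1=10, level2=10, undet1=0, undet2=0, retained=10):
    lcs = {}
    for allele in ("hap1", "hap2"):
        lcs[allele] = level_counts(
            3,
            {1: {0b001: level1}, 2: {0b011: level2}},
            undetermined={1: undet1, 2: undet2},
            allele=allele,
        )
    ret = {a: {0: retained, 1: retained, 2: retained} for a in ("hap1", "hap2")}
    return lcs, ret


def test_triple_filters_boundaries():
    lcs, ret = make_triple_inputs()
    assert passes_triple_filters(lcs, ret)  # exactly 10 everywhere passes
    lcs, ret = make_triple_inputs(level2=9)
    assert not passes_triple_filters(lcs, ret)
    lcs, ret = make_triple_inputs(level1=20, undet1=10)
    assert not passes_triple_filters(lcs, ret)  # 20 is not > 2 x 10
    lcs, ret = make_triple_inputs(level1=21, undet1=10)
    assert passes_triple_filters(lcs, ret)
    lcs, ret = make_triple_inputs(retained=9)
    assert not passes_triple_filters(lcs, ret)


def test_pair_order_frequency():
    assert pair_order_frequency(30, 10) == 0.75
    assert pair_order_frequency(0, 10) == 0.0
    assert pair_order_frequency(7, 7) == 0.5
    with pytest.raises(ValueError):
        pair_order_frequency(0, 0)


def test_intron_group_validation():
    with pytest.raises(ValueError):
        IntronGroup("g", (2, 1, 3))
    with pytest.raises(ValueError):
        IntronGroup("g", (1,))
    assert IntronGroup("g", (4, 5, 6)).group_id == "g:4-5-6"
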