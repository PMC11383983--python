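"""Allele-comparison statistics against brute-force oracles, threshold
calibration, and the difference-class taxonomy."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from splicord.allele_comparison import (
    DEFAULT_TAU,
    REVERSAL_FIRST_AND_LAST,
    REVERSAL_FIRST_OR_LAST_TWO,
    REVERSAL_THREE,
    SAME_ORDER,
    bh_adjust,
    calibrate_threshold,
    call_allele_specific,
    chi_square_level_test,
    classify_difference,
    euclidean_distance,
    fisher_pair_test,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def hypergeom_pmf(a, r1, r2, c1):
    """P(top-left = a) for fixed margins, by binomial coefficients."""
    n = r1 + r2
    return math.comb(r1, a) * math.comb(r2, c1 - a) / math.comb(n, c1)


def fisher_oracle(table):
    """Two-sided Fisher p: sum of all tables (same margins) with
    probability <= the observed table's."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    p_obs = hypergeom_pmf(a, r1, r2, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = hypergeom_pmf(x, r1, r2, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def chi2_oracle(table):
    """Textbook Pearson statistic sum (O-E)^2 / E from the margins."""
    arr = np.asarray(table, float)
    rows, cols = arr.sum(1), arr.sum(0)
    n = arr.sum()
    expected = np.outer(rows, cols) / n
    return float(((arr - expected) ** 2 / expected).sum())


def bh_oracle(pvals):
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank, i in list(enumerate(order, start=1))[::-1]:
        prev = min(prev, pvals[i] * m / rank)
        adj[i] = prev
    return adj


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------

def test_fisher_extreme_table_by_enumeration():
    # [[10,0],[0,10]]: the two extreme tables out of C(20,10) arrangements
    p, effect = fisher_pair_test((10, 0), (0, 10))
    assert p == pytest.approx(2 / 184756, rel=1e-9)
    assert effect == 1.0


def test_fisher_identical_rows():
    p, effect = fisher_pair_test((12, 8), (12, 8))
    assert p == 1.0 and effect == 0.0


def test_fisher_effect_is_frequency_difference():
    p, effect = fisher_pair_test((30, 10), (10, 30))
    assert effect == pytest.approx(0.5)
    assert p == pytest.approx(fisher_oracle([[30, 10], [10, 30]]), rel=1e-9)


def test_fisher_zero_total_allele_rejected():
    with pytest.raises(ValueError):
        fisher_pair_test((0, 0), (5, 5))


def test_fisher_matches_oracle_on_random_small_tables():
    rng = np.random.default_rng(23)
    for _ in range(200):
        table = rng.integers(0, 11, size=(2, 2))
        if table.sum(1).min() == 0:
            continue
        p, _ = fisher_pair_test(tuple(table[0]), tuple(table[1]))
        assert p == pytest.approx(fisher_oracle(table.tolist()), rel=1e-8)


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def test_chi2_closed_form_2x2():
    stat, p, dof = chi_square_level_test([[30, 10, 0], [10, 30, 0]])
    # zero column dropped; n(ad-bc)^2 / (r1 r2 c1 c2) = 20
    assert stat == pytest.approx(20.0)
    assert dof == 1
    assert p == pytest.approx(sps.chi2.sf(20.0, 1))


def test_chi2_identical_rows_and_uniform():
    stat, p, _ = chi_square_level_test([[5, 5, 5], [5, 5, 5]])
    assert stat == 0.0 and p == 1.0


def test_chi2_untestable_tables():
    assert chi_square_level_test([[10, 0], [5, 0]]) is None      # one column
    assert chi_square_level_test([[0, 0, 0], [1, 2, 3]]) is None  # empty row


def test_chi2_matches_textbook_oracle_on_random_tables():
    rng = np.random.default_rng(29)
    for _ in range(200):
        m = int(rng.integers(2, 4))
        table = rng.integers(1, 14, size=(2, m))
        stat, _, _ = chi_square_level_test(table.tolist())
        assert stat == pytest.approx(chi2_oracle(table), rel=1e-9)


# ---------------------------------------------------------------------------
# BH, distance, threshold, call
# ---------------------------------------------------------------------------

def test_bh_worked_example():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_single_and_constant():
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3] * 3)


def test_bh_matches_stepup_oracle():
    rng = np.random.default_rng(31)
    for _ in range(50):
        p = rng.uniform(size=int(rng.integers(1, 20)))
        assert bh_adjust(p) == pytest.approx(bh_oracle(p))


def test_distance_closed_forms():
    assert euclidean_distance([1, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0]) == 0.0
    assert euclidean_distance([1, 0, 0, 0, 0, 0], [0, 1, 0, 0, 0, 0]) == pytest.approx(math.sqrt(2))
    assert euclidean_distance([0.5, 0.5, 0, 0, 0, 0], [0, 0, 1, 0, 0, 0]) == pytest.approx(math.sqrt(1.5))


def test_distance_metric_properties():
    rng = np.random.default_rng(37)
    for _ in range(50):
        a, b, c = (rng.dirichlet(np.ones(6)) for _ in range(3))
        assert euclidean_distance(a, b) == pytest.approx(euclidean_distance(b, a))
        assert euclidean_distance(a, c) <= euclidean_distance(a, b) + euclidean_distance(b, c) + 1e-12
        assert euclidean_distance(a, b) <= math.sqrt(2) + 1e-12


def test_calibrate_threshold_linear_interpolation():
    assert calibrate_threshold([0.1, 0.2, 0.3, 0.4]) == pytest.approx(0.225)
    assert calibrate_threshold([0.3, 0.3, 0.3, 0.3]) == 0.0
    with pytest.raises(ValueError):
        calibrate_threshold([0.1, 0.2, 0.3])
    assert DEFAULT_TAU == 0.379


@pytest.mark.parametrize(
    "d, fdrs, expected",
    [
        (0.5, (0.01, 0.2), True),
        (0.379, (0.001, 0.001), False),  # strictly greater than tau
        (1.0, (0.2, 0.2), False),
        (0.4, (float("nan"), 0.01), True),
        (0.4, (float("nan"), float("nan")), False),
    ],
)
def test_call_rule(d, fdrs, expected):
    assert call_allele_specific(d, fdrs) is expected


# ---------------------------------------------------------------------------
# difference classes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((0, 1, 2), (1, 0, 2), REVERSAL_FIRST_OR_LAST_TWO),
        ((0, 1, 2), (0, 2, 1), REVERSAL_FIRST_OR_LAST_TWO),
        ((0, 1, 2), (2, 1, 0), REVERSAL_FIRST_AND_LAST),
        ((0, 1, 2), (1, 2, 0), REVERSAL_THREE),
        ((0, 1, 2), (2, 0, 1), REVERSAL_THREE),
        ((0, 1, 2), (0, 1, 2), SAME_ORDER),
    ],
)
def test_difference_classes(a, b, expected):
    assert classify_difference(a, b) == expected


def test_difference_classes_cover_all_permutation_pairs():
    for a in itertools.permutations(range(3)):
        for b in itertools.permutations(range(3)):
            assert classify_difference(a, b) in {
                REVERSAL_FIRST_OR_LAST_TWO, REVERSAL_FIRST_AND_LAST,
                REVERSAL_THREE, SAME_ORDER,
            }
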