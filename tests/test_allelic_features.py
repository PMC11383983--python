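"""Per-gene feature comparisons: exact-test oracles, filter boundaries,
label symmetry and call rules."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from splicord.allelic_features import (
    allelic_ratio_and_skew,
    compare_polya,
    compare_three_prime_ends,
    compartment_ratio_correlation,
    feature_tables,
    passes_gene_filters,
    polya_skew_enrichment,
    rank_sum_test,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def wilcoxon_exact_oracle(x, y):
    """Two-sided exact rank-sum p by enumerating all C(n+m, n) rank splits."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n, m = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, n + m + 1), n):
        us.append(sum(combo) - n * (n + 1) / 2)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


def binom_two_sided_oracle(k, n):
    """Sum of outcome probabilities no larger than the observed one."""
    pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    return min(1.0, sum(p for p in pmf if p <= pmf[k] * (1 + 1e-12)))


# ---------------------------------------------------------------------------
# rank-sum
# ---------------------------------------------------------------------------

def test_ranksum_small_sample_enumeration():
    # {1,2,3} vs {4,5,6}: most extreme split of C(6,3)=20 -> p = 2/20
    _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)


def test_ranksum_identical_samples():
    _, p = rank_sum_test([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
    assert p == 1.0


def test_ranksum_matches_enumeration_oracle():
    rng = np.random.default_rng(43)
    for _ in range(40):
        n, m = rng.integers(3, 7, size=2)
        vals = rng.permutation(100)[: n + m].astype(float)
        x, y = vals[:n], vals[n:]
        _, p = rank_sum_test(x, y)
        assert p == pytest.approx(wilcoxon_exact_oracle(list(x), list(y)), rel=1e-9)


def test_polya_power_at_reported_effect():
    """233 vs 143 nt means, sd 30, 200 reads/allele: detected in >=95% of
    simulation replicates."""
    rng = np.random.default_rng(47)
    hits = 0
    n_rep = 60
    for _ in range(n_rep):
        t1 = rng.normal(233, 30, 200)
        t2 = rng.normal(143, 30, 200)
        fc = compare_polya(t1, t2)
        if fc.p < 0.05:
            hits += 1
    assert hits >= 0.95 * n_rep


# ---------------------------------------------------------------------------
# gene filters
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n1, n2, undet, expected",
    [
        (21, 21, 10, True),
        (20, 25, 0, False),   # strictly more than 20 on each allele
        (30, 30, 16, False),  # 30 < 2 x 16
        (30, 30, 15, True),
    ],
)
def test_gene_filters(n1, n2, undet, expected):
    assert passes_gene_filters(n1, n2, undet) is expected


def test_abundance_filter_allows_one_deep_allele():
    assert passes_gene_filters(40, 5, 2, require_both=False)
    assert not passes_gene_filters(40, 3, 2, require_both=False)  # 3 < 2x2


# ---------------------------------------------------------------------------
# 3' ends and abundance
# ---------------------------------------------------------------------------

def test_three_prime_effect_is_mean_shift():
    fc = compare_three_prime_ends([100.0] * 30, [109.5] * 2 + [100.0] * 28)
    assert abs(fc.effect) < 10  # below the APA shift rule


def test_binomial_skew_values():
    fc = allelic_ratio_and_skew(60, 40)
    assert fc.effect == pytest.approx(0.6)
    assert fc.p == pytest.approx(binom_two_sided_oracle(60, 100), rel=1e-9)
    assert fc.p == pytest.approx(0.0569, abs=5e-5)
    even = allelic_ratio_and_skew(50, 50)
    assert even.effect == 0.5 and even.p == 1.0


def test_binomial_matches_oracle_over_grid():
    for n in (10, 25, 40):
        for k in range(n + 1):
            fc = allelic_ratio_and_skew(k, n - k)
            assert fc.p == pytest.approx(binom_two_sided_oracle(k, n), rel=1e-9)


def test_ratio_call_requires_bounds_and_fdr():
    reads = []
    for gene, (n1, n2) in {"g1": (60, 40), "g2": (90, 20)}.items():
        reads += [{"gene_id": gene, "allele": "hap1", "polya_nt": np.nan,
                   "end_pos": 0.0, "splice_state": "all_spliced"}] * n1
        reads += [{"gene_id": gene, "allele": "hap2", "polya_nt": np.nan,
                   "end_pos": 0.0, "splice_state": "all_spliced"}] * n2
    out = feature_tables(pd.DataFrame(reads))["abundance"].set_index("gene_id")
    # r = 0.6 is not > 0.6: never called regardless of p
    assert not out.loc["g1", "call"]
    assert out.loc["g2", "call"]


def test_allele_swap_symmetry():
    rng = np.random.default_rng(53)
    t1, t2 = rng.normal(200, 30, 40), rng.normal(180, 30, 40)
    a = compare_polya(t1, t2)
    b = compare_polya(t2, t1)
    assert a.p == pytest.approx(b.p)
    assert a.effect == pytest.approx(-b.effect)
    r1 = allelic_ratio_and_skew(70, 30)
    r2 = allelic_ratio_and_skew(30, 70)
    assert r1.effect == pytest.approx(1 - r2.effect)
    assert r1.p == pytest.approx(r2.p)


# ---------------------------------------------------------------------------
# enrichment and compartment correlation
# ---------------------------------------------------------------------------

def test_enrichment_odds_ratio_and_oracle_p():
    table = pd.DataFrame(
        {
            "polya_call": [True] * 25 + [False] * 50,
            "skew_call": [True] * 20 + [False] * 5 + [True] * 10 + [False] * 40,
        }
    )
    odds, p = polya_skew_enrichment(table)
    assert odds == pytest.approx(16.0)
    from scipy.stats import fisher_exact

    assert p == pytest.approx(fisher_exact([[20, 5], [10, 40]])[1])


def test_enrichment_empty_margin_rejected():
    table = pd.DataFrame({"polya_call": [True, True], "skew_call": [True, False]})
    with pytest.raises(ValueError):
        polya_skew_enrichment(table)


def test_compartment_correlation_recovers_generative_r():
    rng = np.random.default_rng(59)
    rho = 0.7
    z = rng.normal(size=500)
    x = 0.5 + 0.1 * z
    y = 0.5 + 0.1 * (rho * z + math.sqrt(1 - rho**2) * rng.normal(size=500))
    assert compartment_ratio_correlation(x, x) == pytest.approx(1.0)
    assert compartment_ratio_correlation(x, 1 - x) == pytest.approx(-1.0)
    assert compartment_ratio_correlation(x, y) == pytest.approx(rho, abs=0.05)
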