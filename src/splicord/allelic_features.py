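"""Allele-level comparisons of poly(A) tail length, 3'-end position and
transcript abundance.

Per gene, reads assigned to each haplotype are compared feature by feature:

* poly(A) tails — two-sided Wilcoxon rank-sum test on per-read tail lengths
  (exact null distribution when both samples are small and tie-free, normal
  approximation with tie/continuity correction otherwise), BH across genes,
  call at FDR < 0.05; optionally stratified by read splice state (all reads,
  fully spliced only, partially spliced only).
* 3'-end positions — same rank-sum test on strand-resolved genomic 3'-end
  coordinates; a call additionally requires at least 10 nt between the
  allele mean 3'-end positions (alternative polyadenylation).
* abundance — allelic ratio r = n1 / (n1 + n2) with an exact two-sided
  binomial test against 0.5; a gene is skewed at FDR < 0.05 with r < 0.4 or
  r > 0.6. A softer "nominal skew" flag (p < 0.01, r outside 0.45..0.55) is
  also reported.

Gene coverage filters: poly(A) and 3'-end comparisons need more than 20
reads on each allele; abundance needs more than 20 reads on either allele;
all require per-allele counts at least twice the undetermined count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allele_comparison import bh_adjust
from .intron_status import ALL_SPLICED, PARTIALLY_SPLICED

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class FeatureComparison:
    gene_id: str
    feature: str
    statistic: float
    p: float
    effect: float  # median tail shift / mean end shift / allelic ratio
    n_hap1: int
    n_hap2: int


def passes_gene_filters(
    n_hap1: int, n_hap2: int, n_undetermined: int,
    min_reads: int = 20, require_both: bool = True,
) -> bool:
    """Strictly more than ``min_reads`` on each allele (or on either, for
    abundance) and each allele count at least twice the undetermined count."""
    enough = (n_hap1 > min_reads and n_hap2 > min_reads) if require_both \
        else (n_hap1 > min_reads or n_hap2 > min_reads)
    return enough and n_hap1 >= 2 * n_undetermined and n_hap2 >= 2 * n_undetermined


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact when both samples have <= 25 observations and no cross-sample
    ties; otherwise the normal approximation with continuity and tie
    correction. Returns (U statistic, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    tied = len(np.union1d(x, y)) < x.size + y.size
    method = "exact" if (x.size <= EXACT_WILCOXON_MAX_N and y.size <= EXACT_WILCOXON_MAX_N and not tied) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_polya(
    tails_hap1: Sequence[float], tails_hap2: Sequence[float], gene_id: str = "", feature: str = "polya"
) -> FeatureComparison:
    """Rank-sum comparison of per-read poly(A) tail lengths between alleles."""
    stat, p = rank_sum_test(tails_hap1, tails_hap2)
    effect = float(np.median(tails_hap1) - np.median(tails_hap2))
    return FeatureComparison(gene_id, feature, stat, p, effect, len(tails_hap1), len(tails_hap2))


def compare_polya_by_splice_state(
    reads: pd.DataFrame, gene_id: str = "",
    min_reads: int = 20,
) -> list[FeatureComparison]:
    """Poly(A) comparison for all reads / fully spliced / partially spliced.

    ``reads`` columns: allele, polya_nt, splice_state. Each class applies the
    gene coverage filter to its own reads; classes failing it are skipped.
    """
    out = []
    classes = {
        "polya_all": reads,
        "polya_all_spliced": reads[reads["splice_state"] == ALL_SPLICED],
        "polya_partially_spliced": reads[reads["splice_state"] == PARTIALLY_SPLICED],
    }
    for feature, sub in classes.items():
        sub = sub.dropna(subset=["polya_nt"])
        t1 = sub.loc[sub["allele"] == "hap1", "polya_nt"].to_numpy()
        t2 = sub.loc[sub["allele"] == "hap2", "polya_nt"].to_numpy()
        n_undet = int((sub["allele"] == "undetermined").sum())
        if not passes_gene_filters(t1.size, t2.size, n_undet, min_reads=min_reads):
            continue
        out.append(compare_polya(t1, t2, gene_id=gene_id, feature=feature))
    return out


def compare_three_prime_ends(
    ends_hap1: Sequence[float], ends_hap2: Sequence[float], gene_id: str = ""
) -> FeatureComparison:
    """Rank-sum comparison of strand-resolved 3'-end positions.

    The effect is the difference of allele mean 3'-end positions; the APA
    call (made by the caller after BH) requires |effect| >= 10 nt.
    """
    stat, p = rank_sum_test(ends_hap1, ends_hap2)
    effect = float(np.mean(ends_hap1) - np.mean(ends_hap2))
    return FeatureComparison(gene_id, "three_prime_end", stat, p, effect, len(ends_hap1), len(ends_hap2))


def allelic_ratio_and_skew(n_hap1: int, n_hap2: int, gene_id: str = "") -> FeatureComparison:
    """Allelic ratio and exact two-sided binomial test against p = 0.5."""
    n = n_hap1 + n_hap2
    if n == 0:
        raise ValueError("no allele-assigned reads")
    p = float(stats.binomtest(n_hap1, n, 0.5, alternative="two-sided").pvalue)
    r = n_hap1 / n
    return FeatureComparison(gene_id, "abundance", float(n_hap1), p, r, n_hap1, n_hap2)


def polya_skew_enrichment(gene_table: pd.DataFrame) -> tuple[float, float]:
    """Fisher's exact test: are allele-specific-poly(A) genes enriched among
    abundance-skewed genes?

    ``gene_table`` needs boolean columns ``polya_call`` and ``skew_call``.
    Returns (odds ratio, two-sided p). Raises on an empty margin.
    """
    a = int((gene_table["polya_call"] & gene_table["skew_call"]).sum())
    b = int((gene_table["polya_call"] & ~gene_table["skew_call"]).sum())
    c = int((~gene_table["polya_call"] & gene_table["skew_call"]).sum())
    d = int((~gene_table["polya_call"] & ~gene_table["skew_call"]).sum())
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("empty margin: enrichment not testable")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def compartment_ratio_correlation(
    ratios_chromatin: Sequence[float], ratios_cytoplasm: Sequence[float]
) -> float:
    """Pearson correlation of per-gene allelic ratios between compartments."""
    r, _ = stats.pearsonr(np.asarray(ratios_chromatin, float), np.asarray(ratios_cytoplasm, float))
    return float(r)


def feature_tables(
    reads: pd.DataFrame,
    min_reads: int = 20,
    fdr: float = 0.05,
    end_shift_min: float = 10.0,
    ratio_bounds: tuple[float, float] = (0.4, 0.6),
    nominal_p: float = 0.01,
    nominal_bounds: tuple[float, float] = (0.45, 0.55),
) -> dict[str, pd.DataFrame]:
    """Per-gene feature comparisons over a full read table.

    ``reads`` columns: gene_id, allele, polya_nt, end_pos, splice_state.
    Returns TSV-ready DataFrames keyed 'polya', 'ends', 'abundance'; BH is
    applied per feature across genes (splice-state strata of the poly(A)
    comparison share the poly(A) family).
    """
    polya_rows, end_rows, abund_rows = [], [], []
    for gene_id, sub in reads.groupby("gene_id", sort=True):
        n1 = int((sub["allele"] == "hap1").sum())
        n2 = int((sub["allele"] == "hap2").sum())
        nu = int((sub["allele"] == "undetermined").sum())
        for fc in compare_polya_by_splice_state(sub, gene_id=gene_id, min_reads=min_reads):
            polya_rows.append(fc)
        if passes_gene_filters(n1, n2, nu, min_reads=min_reads):
            e1 = sub.loc[sub["allele"] == "hap1", "end_pos"].dropna().to_numpy()
            e2 = sub.loc[sub["allele"] == "hap2", "end_pos"].dropna().to_numpy()
            end_rows.append(compare_three_prime_ends(e1, e2, gene_id=gene_id))
        if passes_gene_filters(n1, n2, nu, min_reads=min_reads, require_both=False):
            abund_rows.append(allelic_ratio_and_skew(n1, n2, gene_id=gene_id))

    def _frame(rows: list[FeatureComparison]) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": fc.gene_id, "feature": fc.feature, "statistic": fc.statistic,
                    "p": fc.p, "effect": fc.effect, "n_hap1": fc.n_hap1, "n_hap2": fc.n_hap2,
                }
                for fc in rows
            ]
        )

    out: dict[str, pd.DataFrame] = {}
    polya = _frame(polya_rows)
    if not polya.empty:
        polya["fdr"] = bh_adjust(polya["p"].to_numpy())
        polya["call"] = polya["fdr"] < fdr
    out["polya"] = polya

    ends = _frame(end_rows)
    if not ends.empty:
        ends["fdr"] = bh_adjust(ends["p"].to_numpy())
        ends["call"] = (ends["fdr"] < fdr) & (ends["effect"].abs() >= end_shift_min)
    out["ends"] = ends

    abund = _frame(abund_rows)
    if not abund.empty:
        abund = abund.rename(columns={"effect": "allelic_ratio"})
        abund["fdr"] = bh_adjust(abund["p"].to_numpy())
        lo, hi = ratio_bounds
        abund["call"] = (abund["fdr"] < fdr) & ((abund["allelic_ratio"] < lo) | (abund["allelic_ratio"] > hi))
        nlo, nhi = nominal_bounds
        abund["nominal_skew"] = (abund["p"] < nominal_p) & (
            (abund["allelic_ratio"] < nlo) | (abund["allelic_ratio"] > nhi)
        )
    out["abundance"] = abund
    return out
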