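"""Splicing-order scores from intermediate-isoform counts.

A group of k consecutive introns (k = 2 or 3) defines, for each read that
spans all of them with a clean excised / not-excised status, an intermediate
isoform: the subset of introns already removed. Reads with L introns removed
sit at splicing level L. Within each level the isoform frequencies
f_k = c_k / sum(c) are recorded; a removal order (a permutation of the group)
is supported by one isoform per intermediate level, and its raw score is the
product of those frequencies along the path,

    P_i = prod_L f_{pattern_i(L)}      (levels 0 and k contribute 1),

normalized over the group's observed orders so that sum_i p_i = 1. For
triples the path has 4 nodes (nothing removed, one, two, all three) and 6
possible orders, reported in a fixed lexicographic slot order so vectors are
comparable across alleles.

Coverage filters (per allele, counting only allele-assigned reads) mirror
the intended use on chromatin-associated direct-RNA data: pairs need more
than 10 spanning reads per allele; triples need every intron retained in at
least 10 reads, at least 10 spanning reads at each intermediate level, and
at each level more reads per allele than twice the undetermined reads.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intron_status import EXCISED, NOT_EXCISED

Pattern = int  # bitmask over the group's introns, bit i set = intron i excised
Order = tuple[int, ...]  # permutation of range(k): removal order


def canonical_orders(k: int) -> list[Order]:
    """All removal orders in lexicographic (canonical slot) order."""
    return sorted(itertools.permutations(range(k)))


def patterns_at_level(k: int, level: int) -> list[Pattern]:
    """All level-``level`` bitmask patterns, sorted."""
    return sorted(
        sum(1 << i for i in combo) for combo in itertools.combinations(range(k), level)
    )


def pattern_of_order(order: Order, level: int) -> Pattern:
    return sum(1 << i for i in order[:level])


def pattern_label(pattern: Pattern, k: int) -> str:
    """Bit string 5'->3', e.g. '101' = introns 1 and 3 of a triple excised."""
    return "".join("1" if pattern >> i & 1 else "0" for i in range(k))


def order_label(order: Order) -> str:
    return "->".join(str(i + 1) for i in order)


@dataclass(frozen=True)
class IntronGroup:
    gene_id: str
    intron_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = self.intron_indices
        if len(idx) not in (2, 3):
            raise ValueError("intron groups hold 2 or 3 introns")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("intron indices must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.intron_indices)

    @property
    def group_id(self) -> str:
        return f"{self.gene_id}:{'-'.join(map(str, self.intron_indices))}"


@dataclass
class LevelCounts:
    """Read counts per intermediate isoform, per splicing level, one allele."""

    group_id: str
    allele: str
    k: int
    counts: dict[int, dict[Pattern, int]] = field(default_factory=dict)
    undetermined: dict[int, int] = field(default_factory=dict)  # level -> count

    def total(self, level: int) -> int:
        return sum(self.counts.get(level, {}).values())

    def frequencies(self, level: int) -> dict[Pattern, float]:
        """f_k = c_k / sum(c) over patterns at one level; {} if no reads."""
        lv = self.counts.get(level, {})
        tot = sum(lv.values())
        if tot == 0:
            return {}
        return {pat: c / tot for pat, c in lv.items() if c > 0}


@dataclass(frozen=True)
class OrderScoreVector:
    group_id: str
    allele: str
    orders: tuple[Order, ...]
    raw: tuple[float, ...]
    scores: tuple[float, ...]
    scorable: bool

    def as_dict(self) -> dict[str, float]:
        return {order_label(o): s for o, s in zip(self.orders, self.scores)}


def spanning_patterns(
    group: IntronGroup, status_df: pd.DataFrame
) -> pd.Series:
    """Per-read intermediate-isoform bitmask for reads spanning the group.

    ``status_df`` is the long status table (read_id, gene_id, intron_index,
    status). A read qualifies only if every intron of the group has status
    excised or not_excised in that read; skipped/undetermined introns or
    missing coverage exclude the read.
    """
    sub = status_df[
        (status_df["gene_id"] == group.gene_id)
        & (status_df["intron_index"].isin(group.intron_indices))
    ]
    piv = sub.pivot_table(
        index="read_id", columns="intron_index", values="status", aggfunc="first"
    )
    for idx in group.intron_indices:
        if idx not in piv.columns:
            return pd.Series(dtype=int)
    piv = piv[list(group.intron_indices)].dropna()
    ok = piv.isin([EXCISED, NOT_EXCISED]).all(axis=1)
    piv = piv[ok]
    masks = sum(
        (piv[idx] == EXCISED).astype(int) * (1 << bit)
        for bit, idx in enumerate(group.intron_indices)
    )
    return masks.sort_index()


def count_levels(
    group: IntronGroup,
    patterns_by_read: pd.Series,
    allele_by_read: Mapping[str, str],
    alleles: Sequence[str] = ("hap1", "hap2"),
) -> dict[str, LevelCounts]:
    """Split spanning-read patterns into per-allele level counts.

    Reads whose allele is missing or not in ``alleles`` accrue to the
    'undetermined' tally of their splicing level on every allele's record
    (the undetermined pool is shared between alleles).
    """
    k = group.k
    out = {
        a: LevelCounts(group.group_id, a, k, {L: {} for L in range(k + 1)}, {L: 0 for L in range(k + 1)})
        for a in alleles
    }
    for read_id, pat in patterns_by_read.items():
        level = bin(int(pat)).count("1")
        allele = allele_by_read.get(read_id, "undetermined")
        if allele in out:
            lv = out[allele].counts[level]
            lv[int(pat)] = lv.get(int(pat), 0) + 1
        else:
            for lc in out.values():
                lc.undetermined[level] += 1
    return out


def pair_order_frequency(up_first: int, down_first: int) -> float:
    """Fraction of order-informative reads with the upstream intron out first."""
    tot = up_first + down_first
    if tot == 0:
        raise ValueError("no order-informative reads")
    return up_first / tot


def passes_pair_filters(
    n_hap1: int, n_hap2: int, n_undetermined: int, min_reads: int = 10
) -> bool:
    """Pairs: strictly more than ``min_reads`` spanning reads per allele and
    more reads per allele than twice the undetermined reads."""
    return all(n > min_reads and n > 2 * n_undetermined for n in (n_hap1, n_hap2))


def passes_triple_filters(
    level_counts: Mapping[str, LevelCounts],
    retained_reads: Mapping[str, Mapping[int, int]],
    min_reads: int = 10,
) -> bool:
    """Triples, per allele: 1) every intron retained in >= min_reads reads;
    2) >= min_reads spanning reads at each intermediate level (1..k-1);
    3) at each intermediate level, more reads than twice the undetermined
    reads at that level.

    ``retained_reads`` maps allele -> {intron_index: n reads with that intron
    not excised} (any read covering the intron, not only group-spanning ones).
    """
    for allele, lc in level_counts.items():
        ret = retained_reads.get(allele, {})
        if any(n < min_reads for n in ret.values()) or not ret:
            return False
        for level in range(1, lc.k):
            n = lc.total(level)
            if n < min_reads:
                return False
            if n <= 2 * lc.undetermined.get(level, 0):
                return False
    return True


def scores_from_frequencies(
    freqs: Mapping[int, Mapping[Pattern, float]], k: int,
    group_id: str = "", allele: str = "",
) -> OrderScoreVector:
    """Score vector from per-level intermediate-isoform frequencies.

    ``freqs[L][pattern]`` is f at intermediate level L (1..k-1); the trivial
    levels 0 and k contribute a factor of 1 along every path.
    """
    orders = canonical_orders(k)
    raw = []
    for order in orders:
        p = 1.0
        for level in range(1, k):
            p *= freqs.get(level, {}).get(pattern_of_order(order, level), 0.0)
        raw.append(p)
    total = sum(raw)
    if total == 0:
        return OrderScoreVector(
            group_id, allele, tuple(orders), tuple(raw),
            tuple(0.0 for _ in raw), scorable=False,
        )
    return OrderScoreVector(
        group_id, allele, tuple(orders), tuple(raw),
        tuple(r / total for r in raw), scorable=True,
    )


def order_scores(level_counts: LevelCounts) -> OrderScoreVector:
    """Normalized splicing-order scores for one allele of one intron group.

    Every possible order gets a slot; orders whose path is unobserved score
    zero. If no order has support (some intermediate level empty, or no
    pattern chain is consistent) the vector is flagged unscorable rather
    than returned as NaNs.
    """
    k = level_counts.k
    freqs = {L: level_counts.frequencies(L) for L in range(1, k)}
    return scores_from_frequencies(
        freqs, k, group_id=level_counts.group_id, allele=level_counts.allele
    )


def retained_read_counts(
    status_df: pd.DataFrame,
    allele_by_read: Mapping[str, str],
    gene_id: str,
    intron_indices: Iterable[int],
    alleles: Sequence[str] = ("hap1", "hap2"),
) -> dict[str, dict[int, int]]:
    """Reads (any read covering the intron) with status not_excised,
    per allele and intron — feeds triple filter (1)."""
    sub = status_df[
        (status_df["gene_id"] == gene_id)
        & (status_df["intron_index"].isin(list(intron_indices)))
        & (status_df["status"] == NOT_EXCISED)
    ]
    out: dict[str, dict[int, int]] = {a: {int(i): 0 for i in intron_indices} for a in alleles}
    for _, row in sub.iterrows():
        allele = allele_by_read.get(row["read_id"])
        if allele in out:
            out[allele][int(row["intron_index"])] += 1
    return out


def consecutive_triples(intron_indices: Sequence[int], gene_id: str) -> list[IntronGroup]:
    """All windows of three consecutive analyzed introns of one transcript.

    Groups duplicated across transcripts (identical genomic coordinates)
    should be deduplicated by the caller keeping one instance.
    """
    idx = sorted(set(int(i) for i in intron_indices))
    groups = []
    for a, b, c in zip(idx, idx[1:], idx[2:]):
        if b == a + 1 and c == b + 1:
            groups.append(IntronGroup(gene_id, (a, b, c)))
    return groups


def pair_counts_from_patterns(
    patterns_by_read: pd.Series, allele_by_read: Mapping[str, str]
) -> dict[str, tuple[int, int]]:
    """(upstream-first, downstream-first) counts per allele for a 2-intron
    group: reads with exactly one of the two introns excised."""
    counts: dict[str, list[int]] = {}
    for read_id, pat in patterns_by_read.items():
        pat = int(pat)
        if pat == 0b01:
            slot = 0
        elif pat == 0b10:
            slot = 1
        else:
            continue
        allele = allele_by_read.get(read_id, "undetermined")
        counts.setdefault(allele, [0, 0])[slot] += 1
    return {a: (c[0], c[1]) for a, c in counts.items()}
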