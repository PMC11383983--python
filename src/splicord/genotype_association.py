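"""Genotype / splicing-order association across samples.

Each allele of each cell line is treated as one sample, with genotype 0 for
the reference allele and 2 for the alternative allele at every SNP in the
gene (plus 500 nt flanks). SNPs sharing an identical genotype vector across
allele-samples form one haplotype block and are tested together.

The association test here is a deliberately simple pooled chi-square: at one
splicing level, intermediate-isoform counts are summed within the
genotype-0 and genotype-2 allele groups and compared with a Pearson
contingency test, BH-corrected across all tested (block, group, level)
triples. This is NOT a Dirichlet-multinomial transcript-usage fit — it
ignores overdispersion between samples — and output columns are prefixed
``chi2_pooled_`` to say so.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .allele_comparison import bh_adjust, chi_square_level_test

REF_GENOTYPE = 0
ALT_GENOTYPE = 2


@dataclass(frozen=True)
class HaplotypeBlock:
    block_id: str
    snp_ids: tuple[str, ...]
    genotypes: tuple[int, ...]  # one entry per allele-sample, 0 or 2


def group_haplotype_blocks(genotype_matrix: pd.DataFrame) -> list[HaplotypeBlock]:
    """Partition SNPs (rows) into blocks of identical genotype vectors.

    Entries must be 0 (reference) or 2 (alternative); columns are
    allele-samples. The partition is invariant to SNP row order: blocks are
    keyed by genotype vector and named after their first SNP in sorted order.
    """
    if genotype_matrix.empty:
        raise ValueError("need at least one SNP")
    values = genotype_matrix.to_numpy()
    if not np.isin(values, [REF_GENOTYPE, ALT_GENOTYPE]).all():
        raise ValueError("genotype entries must be 0 (ref) or 2 (alt)")
    by_vector: dict[tuple[int, ...], list[str]] = {}
    for snp_id, row in genotype_matrix.iterrows():
        by_vector.setdefault(tuple(int(v) for v in row), []).append(str(snp_id))
    blocks = []
    for vector, snps in by_vector.items():
        snps = sorted(snps)
        blocks.append(HaplotypeBlock(block_id=f"block_{snps[0]}", snp_ids=tuple(snps), genotypes=vector))
    return sorted(blocks, key=lambda b: b.block_id)


def filter_for_association(
    reads_per_sample: Mapping[str, int],
    block: HaplotypeBlock,
    sample_order: Sequence[str],
    min_samples: int = 10,
    min_reads: int = 10,
    min_maf_alleles: int = 2,
) -> bool:
    """Keep a (group, block) pair when at least ``min_samples`` allele-samples
    have >= ``min_reads`` reads and the minor genotype is carried by at least
    ``min_maf_alleles`` of those qualifying samples."""
    geno = dict(zip(sample_order, block.genotypes))
    qualifying = [s for s in sample_order if reads_per_sample.get(s, 0) >= min_reads]
    if len(qualifying) < min_samples:
        return False
    n_ref = sum(1 for s in qualifying if geno[s] == REF_GENOTYPE)
    n_alt = len(qualifying) - n_ref
    return min(n_ref, n_alt) >= min_maf_alleles


def associate_block_with_order(
    block: HaplotypeBlock,
    pattern_counts: pd.DataFrame,
    sample_order: Sequence[str],
) -> Optional[tuple[float, float]]:
    """Pooled chi-square association of one block with one level's counts.

    ``pattern_counts``: rows = allele-samples (index aligned with
    ``sample_order``), columns = intermediate-isoform patterns at one
    splicing level. Counts are pooled within each genotype group and the two
    pooled rows compared. Returns (statistic, p) or None when one genotype
    group is empty or fewer than two informative patterns remain.
    """
    geno = dict(zip(sample_order, block.genotypes))
    ref_rows = [s for s in pattern_counts.index if geno.get(s) == REF_GENOTYPE]
    alt_rows = [s for s in pattern_counts.index if geno.get(s) == ALT_GENOTYPE]
    if not ref_rows or not alt_rows:
        return None
    pooled = [
        pattern_counts.loc[ref_rows].sum(axis=0).to_numpy(),
        pattern_counts.loc[alt_rows].sum(axis=0).to_numpy(),
    ]
    res = chi_square_level_test(pooled)
    if res is None:
        return None
    return res[0], res[1]


def associate_all(
    blocks_by_gene: Mapping[str, Sequence[HaplotypeBlock]],
    counts_by_group_level: Mapping[tuple[str, str, int], pd.DataFrame],
    sample_order: Sequence[str],
    reads_per_sample_by_group: Mapping[str, Mapping[str, int]],
    fdr: float = 0.05,
    min_samples: int = 10,
    min_reads: int = 10,
    min_maf_alleles: int = 2,
) -> pd.DataFrame:
    """Test every retained (block, group, level) triple; BH across them all.

    ``counts_by_group_level`` keys are (gene_id, group_id, level).
    """
    rows = []
    for (gene_id, group_id, level), counts in sorted(counts_by_group_level.items()):
        for block in blocks_by_gene.get(gene_id, []):
            if not filter_for_association(
                reads_per_sample_by_group.get(group_id, {}), block, sample_order,
                min_samples=min_samples, min_reads=min_reads, min_maf_alleles=min_maf_alleles,
            ):
                continue
            res = associate_block_with_order(block, counts, sample_order)
            if res is None:
                continue
            rows.append(
                {
                    "gene_id": gene_id,
                    "group_id": group_id,
                    "level": level,
                    "block_id": block.block_id,
                    "n_snps": len(block.snp_ids),
                    "chi2_pooled_stat": res[0],
                    "chi2_pooled_p": res[1],
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["chi2_pooled_fdr"] = bh_adjust(df["chi2_pooled_p"].to_numpy())
        df["significant"] = df["chi2_pooled_fdr"] < fdr
    return df
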