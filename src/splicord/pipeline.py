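"""End-to-end orchestration: SAM + VCF + BED in, one TSV per stage out.

Stages: intron excision status per (read, intron); allele assignment from
phased SNPs; per-group intermediate-isoform counts, coverage filters and
splicing-order scores; allele comparison (chi-square per level, BH,
Euclidean distance, call, difference class); and per-gene feature
comparisons (poly(A), 3' ends, abundance). All thresholds live in RunConfig
with the analysis defaults; the config (and its hash) is serialized into a
run manifest and echoed as '#'-prefixed metadata lines atop every TSV, so
outputs are self-describing and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import re
import time
from dataclasses import dataclass
from typing import Optional

import pandas as pd
import pysam

from . import __version__
from .allele_assignment import PhasedSNP, assign_reads, load_phased_snps
from .allele_comparison import DEFAULT_TAU, compare_groups, compare_pairs
from .allelic_features import feature_tables
from .intron_status import AlignedRead, classify_reads, from_pysam, splice_state_table
from .splicing_order import (
    IntronGroup,
    consecutive_triples,
    count_levels,
    order_label,
    pair_counts_from_patterns,
    passes_pair_filters,
    passes_triple_filters,
    retained_read_counts,
    spanning_patterns,
    order_scores,
)

log = logging.getLogger(__name__)

_BED_NAME = re.compile(r"^(?P<gene>.+)_intron(?P<idx>\d+)$")


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    bam: str = ""
    vcf: str = ""
    annotation: str = ""
    outdir: str = "results"
    ss_window: int = 50
    size_tol: float = 0.10
    tau: float = DEFAULT_TAU
    fdr: float = 0.05
    pair_min_reads: int = 10
    triple_min_reads: int = 10
    gene_min_reads: int = 20
    end_shift_min: float = 10.0
    ratio_bounds: tuple[float, float] = (0.4, 0.6)
    agreement_min: float = 0.75
    min_informative: int = 2
    pair_min_effect: float = 0.1
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        # outdir is a location, not an analysis parameter: runs of the same
        # analysis into different directories must hash identically
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def read_intron_bed(path: str) -> list[tuple[str, int, int, str, str, int]]:
    """BED6 intron track -> (chrom, start, end, gene_id, strand, index).

    Names follow the ``gene_intronN`` convention with N the transcript-order
    intron index.
    """
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    introns = []
    for row in bed.itertuples(index=False):
        m = _BED_NAME.match(str(row.name))
        if not m:
            raise ValueError(f"intron name {row.name!r} does not match gene_intronN")
        introns.append(
            (str(row.chrom), int(row.start), int(row.end), m.group("gene"), str(row.strand), int(m.group("idx")))
        )
    return introns


def read_alignments(path: str) -> list[AlignedRead]:
    """All mapped reads of a SAM/BAM as lightweight AlignedReads."""
    reads = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            reads.append(from_pysam(aln))
    return reads


def _strand_three_prime_end(read: AlignedRead) -> int:
    return read.ref_end if read.strand == "+" else read.aln_start


def write_tsv(df: pd.DataFrame, path: str, config: RunConfig, stage: str) -> None:
    """TSV with '#'-prefixed metadata lines, stable ordering and formatting."""
    with open(path, "w") as fh:
        fh.write(f"# splicord {__version__} stage={stage}\n")
        fh.write(f"# config_hash={config.digest()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def order_score_table(level_counts_by_group: dict[str, dict[str, "LevelCounts"]]) -> pd.DataFrame:
    """Score vectors as one row per (group, allele) with six score columns."""
    rows = []
    for gid in sorted(level_counts_by_group):
        for allele in ("hap1", "hap2"):
            vec = order_scores(level_counts_by_group[gid][allele])
            row = {"group_id": gid, "allele": allele, "scorable": vec.scorable}
            row.update({order_label(o): s for o, s in zip(vec.orders, vec.scores)})
            rows.append(row)
    return pd.DataFrame(rows)


def snps_to_phased(snps_by_chrom) -> list[PhasedSNP]:
    """Simulator SNP tuples (pos, ref, alt) -> PhasedSNP (hap1 = ref)."""
    out = []
    for chrom in sorted(snps_by_chrom):
        for pos, ref, alt in sorted(snps_by_chrom[chrom]):
            out.append(PhasedSNP(f"{chrom}_{pos}", chrom, pos, ref, alt))
    return out


def introns_table(models) -> list[tuple[str, int, int, str, str, int]]:
    """(chrom, start, end, gene_id, strand, index) rows from GeneModels."""
    rows = []
    for m in models:
        for intron in m.introns:
            rows.append((m.chrom, intron[0], intron[1], m.gene_id, m.strand, m.intron_index(intron)))
    return sorted(rows)


def analyze(
    reads: list[AlignedRead],
    introns: list[tuple[str, int, int, str, str, int]],
    snps,
    config: Optional[RunConfig] = None,
) -> dict[str, pd.DataFrame]:
    """All analysis stages over in-memory inputs; returns the result bundle.

    ``snps`` is a sequence of PhasedSNP. File loading and TSV writing live in
    :func:`run_all`; simulation studies call this directly.
    """
    config = config or RunConfig()
    t0 = time.time()
    results: dict[str, pd.DataFrame] = {}

    def _stage(name):
        log.info("stage %-12s %6.2fs", name, time.time() - t0)

    try:
        status = classify_reads(reads, introns, ss_window=config.ss_window, size_tol=config.size_tol)
        status = status.sort_values(["read_id", "gene_id", "intron_index"]).reset_index(drop=True)
        results["status"] = status
        _stage("status")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'status' failed: {exc}") from exc

    try:
        alleles = assign_reads(
            reads, snps, min_informative=config.min_informative, min_agreement=config.agreement_min
        ).sort_values("read_id").reset_index(drop=True)
        results["alleles"] = alleles
        _stage("assign")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'assign' failed: {exc}") from exc

    allele_by_read = dict(zip(alleles["read_id"], alleles["allele"]))

    try:
        gene_introns: dict[str, list[int]] = {}
        for _, _, _, gene, _, idx in introns:
            gene_introns.setdefault(gene, []).append(idx)
        level_counts_by_group: dict[str, dict] = {}
        count_rows = []
        pair_counts_all: dict[str, dict[str, tuple[int, int]]] = {}
        for gene in sorted(gene_introns):
            idxs = sorted(set(gene_introns[gene]))
            for group in consecutive_triples(idxs, gene):
                pats = spanning_patterns(group, status)
                lc = count_levels(group, pats, allele_by_read)
                retained = retained_read_counts(status, allele_by_read, gene, group.intron_indices)
                if passes_triple_filters(lc, retained, min_reads=config.triple_min_reads):
                    level_counts_by_group[group.group_id] = lc
                for allele in ("hap1", "hap2"):
                    for level, by_pat in sorted(lc[allele].counts.items()):
                        for pat, c in sorted(by_pat.items()):
                            count_rows.append(
                                (group.group_id, allele, level, format(pat, f"0{group.k}b")[::-1], c)
                            )
            # consecutive pairs for the Fisher route
            for a, b in zip(idxs, idxs[1:]):
                if b != a + 1:
                    continue
                pair = IntronGroup(gene, (a, b))
                pats = spanning_patterns(pair, status)
                counts = pair_counts_from_patterns(pats, allele_by_read)
                h1 = counts.get("hap1", (0, 0))
                h2 = counts.get("hap2", (0, 0))
                und = sum(counts.get("undetermined", (0, 0)))
                if passes_pair_filters(sum(h1), sum(h2), und, min_reads=config.pair_min_reads):
                    pair_counts_all[pair.group_id] = {"hap1": h1, "hap2": h2}
        results["counts"] = pd.DataFrame(
            count_rows, columns=["group_id", "allele", "level", "pattern", "count"]
        )
        results["orders"] = order_score_table(level_counts_by_group)
        _stage("order")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'order' failed: {exc}") from exc

    try:
        results["comparison"] = compare_groups(level_counts_by_group, tau=config.tau, fdr=config.fdr)
        results["pair_comparison"] = compare_pairs(
            pair_counts_all, fdr=config.fdr, min_effect=config.pair_min_effect
        )
        _stage("compare")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'compare' failed: {exc}") from exc

    try:
        states = splice_state_table(status)
        read_gene = status[["read_id", "gene_id"]].drop_duplicates()
        info = {r.read_id: r for r in reads}
        table = read_gene.merge(states, on=["read_id", "gene_id"], how="left")
        table["splice_state"] = table["splice_state"].fillna("not_classifiable")
        table["allele"] = table["read_id"].map(allele_by_read).fillna("undetermined")
        table["polya_nt"] = table["read_id"].map(lambda r: info[r].polya_nt)
        table["end_pos"] = table["read_id"].map(lambda r: _strand_three_prime_end(info[r]))
        results["read_table"] = table.sort_values("read_id").reset_index(drop=True)
        feats = feature_tables(
            table, min_reads=config.gene_min_reads, fdr=config.fdr,
            end_shift_min=config.end_shift_min, ratio_bounds=config.ratio_bounds,
        )
        results.update(feats)
        _stage("features")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc

    return results


def run_all(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Load inputs, run every stage, write one TSV per stage plus a manifest
    under ``config.outdir``; identical config + inputs give byte-identical
    TSVs."""
    os.makedirs(config.outdir, exist_ok=True)
    try:
        introns = read_intron_bed(config.annotation)
        reads = read_alignments(config.bam)
        snps = load_phased_snps(config.vcf)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    results = analyze(reads, introns, snps, config)

    for name in ("status", "alleles", "counts", "orders", "comparison",
                 "pair_comparison", "read_table", "polya", "ends", "abundance"):
        write_tsv(results[name], os.path.join(config.outdir, f"{name}.tsv"), config, name)
    manifest = {
        "package": "splicord",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "n_reads": len(reads),
        "n_groups_scored": int(len(results["orders"]) // 2),
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results
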