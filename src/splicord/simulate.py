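"""Simulated chromatin-associated direct-RNA reads with known ground truth.

The generator emulates the statistical structure of nascent dnRNA-seq over
multi-intron genes with two phased haplotypes: per-allele splicing-order
mixtures (each read is an intermediate isoform drawn along one removal-order
path), per-allele poly(A) tail lengths (normal, truncated at zero),
per-allele 3'-cleavage-site choice with small jitter, heterozygous exonic
SNPs carried in the read sequence with a per-observation error rate, and a
configurable fraction of reads left unassignable to an allele.

Every read carries a CIGAR exactly consistent with its true excision
pattern (N ops spanning excised introns, M across retained ones), so the
downstream classifiers can be validated against the emitted truth table.

One RNG stream is derived per (gene, allele) from the master seed, making
fixtures reproducible read-for-read.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .gene_model import GeneModel, make_gene_model
from .intron_status import AlignedRead
from .splicing_order import (
    Order,
    OrderScoreVector,
    Pattern,
    canonical_orders,
    order_label,
    pattern_label,
    scores_from_frequencies,
)

BASES = "ACGT"
POLYA_TAG = "pt"
REF_FLANK = 500


def _stable_key(name: str) -> int:
    """Process-independent 31-bit key for seeding per-gene RNG streams."""
    return zlib.crc32(name.encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class AlleleSpec:
    """Generative parameters for one haplotype of one gene.

    ``snps`` lists the gene's phased heterozygous sites as (pos, ref, alt),
    identical between the two specs of a gene; hap1 carries the reference
    base, hap2 the alternative. ``order_mixture`` gives the removal-order
    distribution of the gene's intron group; ``end_sites`` the 3'-cleavage
    positions with weights; ``depth`` the expected read count.
    """

    allele_id: str
    snps: tuple[tuple[int, str, str], ...]
    order_mixture: dict[Order, float]
    polya_mean_sd: tuple[float, float]
    end_sites: tuple[tuple[int, float], ...]
    depth: float

    def __post_init__(self) -> None:
        if self.allele_id not in ("hap1", "hap2"):
            raise ValueError("allele_id must be 'hap1' or 'hap2'")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        w = list(self.order_mixture.values())
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("order_mixture weights must be >= 0 and sum to 1")
        ew = [x for _, x in self.end_sites]
        if any(x < 0 for x in ew) or abs(sum(ew) - 1.0) > 1e-9:
            raise ValueError("end_sites weights must be >= 0 and sum to 1")
        for pos, ref, alt in self.snps:
            if ref == alt or len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"SNP at {pos} must be a single-base heterozygous site")

    def carried_base(self, ref: str, alt: str) -> str:
        return ref if self.allele_id == "hap1" else alt


@dataclass(frozen=True)
class SimRead:
    """One simulated read plus its generative truth."""

    read_id: str
    gene_id: str
    allele: str
    order: Order
    level: int
    pattern: Pattern
    polya_nt: float
    end_pos: int
    aln_start: int
    cigar: tuple[tuple[str, int], ...]
    seq: str
    chrom: str
    strand: str
    assignable: bool

    def to_aligned_read(self) -> AlignedRead:
        return AlignedRead(
            read_id=self.read_id, chrom=self.chrom, strand=self.strand,
            aln_start=self.aln_start, cigar=self.cigar, seq=self.seq,
            polya_nt=self.polya_nt,
        )


def reference_sequence(model: GeneModel, seed: int, flank: int = REF_FLANK) -> tuple[str, int]:
    """Deterministic random reference over the gene span plus flanks.

    Returns (sequence, offset) with offset the genomic position of base 0.
    Shared between alleles: only SNP sites differ between haplotypes.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 7, _stable_key(model.gene_id)])
    offset = max(0, model.start - flank)
    length = model.end + flank - offset
    seq = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
    return seq, offset


def make_snps(
    model: GeneModel, ref_seq: str, offset: int, n_snps: int = 3, seed: int = 0
) -> tuple[tuple[int, str, str], ...]:
    """Heterozygous exonic SNPs, one per exon from the 5' end, mid-exon.

    Exonic placement guarantees M-op coverage in every read regardless of
    its excision pattern.
    """
    if n_snps > len(model.exons):
        raise ValueError("at most one SNP per exon")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 11])
    snps = []
    for (s, e) in model.exons[:n_snps]:
        pos = (s + e) // 2
        ref = ref_seq[pos - offset]
        alt = rng.choice([b for b in BASES if b != ref])
        snps.append((pos, ref, str(alt)))
    return tuple(snps)


def make_allele_specs(
    model: GeneModel,
    seed: int = 0,
    depth: float = 150.0,
    order_mixture_hap1: Optional[Mapping[Order, float]] = None,
    order_mixture_hap2: Optional[Mapping[Order, float]] = None,
    polya_hap1: tuple[float, float] = (180.0, 30.0),
    polya_hap2: tuple[float, float] = (180.0, 30.0),
    end_sites_hap1: Optional[Sequence[tuple[int, float]]] = None,
    end_sites_hap2: Optional[Sequence[tuple[int, float]]] = None,
    n_snps: Optional[int] = None,
) -> tuple[AlleleSpec, AlleleSpec, str, int]:
    """Convenience builder: two AlleleSpecs plus the shared reference.

    Defaults are a null configuration (identical mixtures, tails and end
    sites between alleles): a uniform order mixture, 180 +/- 30 nt tails and
    a single 3' site 50 nt before the annotated gene end. One heterozygous
    SNP per exon by default, so every read observes one SNP more than the
    gene has introns and a single base-calling error cannot on its own push
    agreement below the 75% assignment rule.
    """
    ref_seq, offset = reference_sequence(model, seed)
    if n_snps is None:
        n_snps = len(model.exons)
    snps = make_snps(model, ref_seq, offset, n_snps=n_snps, seed=seed)
    k = model.n_introns
    uniform = {o: 1.0 / len(canonical_orders(k)) for o in canonical_orders(k)}
    default_end = (
        ((model.end - 50, 1.0),) if model.strand == "+" else ((model.start + 50, 1.0),)
    )
    def _mk(allele_id, mixture, polya, ends):
        return AlleleSpec(
            allele_id=allele_id,
            snps=snps,
            order_mixture=dict(mixture if mixture is not None else uniform),
            polya_mean_sd=polya,
            end_sites=tuple(ends) if ends is not None else default_end,
            depth=depth,
        )
    return (
        _mk("hap1", order_mixture_hap1, polya_hap1, end_sites_hap1),
        _mk("hap2", order_mixture_hap2, polya_hap2, end_sites_hap2),
        ref_seq,
        offset,
    )


def implied_level_frequencies(
    mixture: Mapping[Order, float], k: int
) -> dict[int, dict[Pattern, float]]:
    """Intermediate-isoform frequencies implied by an order mixture under
    uniform sampling of splicing levels: at level L, f(pattern) is the total
    weight of orders whose first L removals equal the pattern."""
    freqs: dict[int, dict[Pattern, float]] = {L: {} for L in range(k + 1)}
    for order, w in mixture.items():
        if sorted(order) != list(range(k)):
            raise ValueError(f"order {order} does not permute range({k})")
        for level in range(k + 1):
            pat = sum(1 << i for i in order[:level])
            freqs[level][pat] = freqs[level].get(pat, 0.0) + w
    return freqs


def implied_score_vector(mixture: Mapping[Order, float], k: int) -> OrderScoreVector:
    """The score vector the scorer converges to at infinite depth."""
    return scores_from_frequencies(implied_level_frequencies(mixture, k), k)


def _build_cigar(
    span: tuple[int, int], excised: Sequence[tuple[int, int]]
) -> tuple[tuple[str, int], ...]:
    """M/N ops over [start, end) with N exactly across each excised intron."""
    start, end = span
    ops: list[tuple[str, int]] = []
    cur = start
    for (s, e) in sorted(excised):
        if e <= start or s >= end:
            continue
        if s > cur:
            ops.append(("M", s - cur))
        ops.append(("N", e - s))
        cur = e
    if end > cur:
        ops.append(("M", end - cur))
    return tuple(ops)


def simulate_reads(
    model: GeneModel,
    specs: tuple[AlleleSpec, AlleleSpec],
    seed: int,
    ref_seq: Optional[str] = None,
    ref_offset: Optional[int] = None,
    flip_prob: float = 0.05,
    unassignable_frac: float = 0.10,
    end_jitter_sd: float = 5.0,
    truncation_p: float = 0.0,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Draw reads for both alleles of one gene.

    Per read: a removal order from the allele's mixture, a splicing level
    uniform on 0..k, hence an excision pattern (the first L introns of the
    order); a 3' end from the allele's site mixture with normal jitter; a
    truncated-normal poly(A) length; and a base sequence over the M segments
    carrying the allele's SNP bases, each flipped to the other haplotype's
    base with probability ``flip_prob``. A fraction ``unassignable_frac`` of
    reads carries a base matching neither haplotype at every SNP site and is
    undetermined downstream. Optional geometric 5' truncation (off by
    default) emulates dnRNA-seq 5' degradation.

    Returns the reads and a truth table with one row per emitted read.
    """
    if ref_seq is None or ref_offset is None:
        ref_seq, ref_offset = reference_sequence(model, seed)
    k = model.n_introns
    for spec in specs:
        for order in spec.order_mixture:
            if sorted(order) != list(range(k)):
                raise ValueError(
                    f"mixture order {order} references introns absent from {model.gene_id}"
                )
    introns_tx = model.introns_transcript_order()
    reads: list[SimRead] = []
    truth_rows = []
    gene_key = _stable_key(model.gene_id)
    for allele_idx, spec in enumerate(specs):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, gene_key, allele_idx])
        n_reads = int(rng.poisson(spec.depth))
        orders = list(spec.order_mixture)
        order_w = np.array([spec.order_mixture[o] for o in orders])
        site_pos = np.array([p for p, _ in spec.end_sites])
        site_w = np.array([w for _, w in spec.end_sites])
        mean, sd = spec.polya_mean_sd
        for i in range(n_reads):
            order = orders[int(rng.choice(len(orders), p=order_w))]
            level = int(rng.integers(0, k + 1))
            chosen = order[:level]
            pattern = sum(1 << j for j in chosen)
            excised = [introns_tx[j] for j in chosen]
            end_pos = int(site_pos[int(rng.choice(len(site_pos), p=site_w))])
            end_pos += int(round(rng.normal(0.0, end_jitter_sd)))
            five_prime = model.tss
            if truncation_p > 0:
                trunc = int(rng.geometric(truncation_p)) - 1
                five_prime = five_prime + trunc if model.strand == "+" else five_prime - trunc
            span = (min(five_prime, end_pos), max(five_prime, end_pos))
            span = (max(span[0], ref_offset), min(span[1], ref_offset + len(ref_seq)))
            cigar = _build_cigar(span, excised)
            polya = max(0.0, float(rng.normal(mean, sd)))
            assignable = bool(rng.random() >= unassignable_frac)
            # sequence over M segments, haplotype bases at SNP sites
            snp_base = {}
            for pos, ref, alt in spec.snps:
                base = spec.carried_base(ref, alt)
                if not assignable:
                    base = next(b for b in BASES if b not in (ref, alt))
                elif flip_prob > 0 and rng.random() < flip_prob:
                    base = alt if base == ref else ref
                snp_base[pos] = base
            chunks = []
            pos = span[0]
            for op, ln in cigar:
                if op == "M":
                    seg = list(ref_seq[pos - ref_offset : pos + ln - ref_offset])
                    for sp, b in snp_base.items():
                        if pos <= sp < pos + ln:
                            seg[sp - pos] = b
                    chunks.append("".join(seg))
                    pos += ln
                else:
                    pos += ln
            read_id = f"{model.gene_id}_{spec.allele_id}_{i:05d}"
            read = SimRead(
                read_id=read_id, gene_id=model.gene_id, allele=spec.allele_id,
                order=order, level=level, pattern=pattern, polya_nt=round(polya, 2),
                end_pos=end_pos if model.strand == "+" else span[0],
                aln_start=span[0], cigar=cigar, seq="".join(chunks),
                chrom=model.chrom, strand=model.strand, assignable=assignable,
            )
            reads.append(read)
            truth_rows.append(
                {
                    "read_id": read_id, "gene_id": model.gene_id,
                    "allele": spec.allele_id, "order": order_label(order),
                    "level": level, "pattern": pattern_label(pattern, k),
                    "polya_nt": read.polya_nt, "end_pos": read.end_pos,
                    "assignable": assignable,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def write_fixture(
    reads: Sequence[SimRead],
    truth: pd.DataFrame,
    models: Sequence[GeneModel],
    snps_by_chrom: Mapping[str, Sequence[tuple[int, str, str]]],
    outdir: str,
    sample: str = "sample1",
) -> dict[str, str]:
    """Write the complete fixture: coordinate-sorted SAM with per-read
    poly(A) tag, phased VCF (GT 0|1), BED6 intron track and truth TSV.

    Files round-trip through the package's readers. Returns the paths.
    """
    if not reads:
        raise ValueError("no reads to write")
    if truth.empty:
        raise ValueError("empty truth table")
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "sam": os.path.join(outdir, "reads.sam"),
        "vcf": os.path.join(outdir, "variants.vcf"),
        "bed": os.path.join(outdir, "introns.bed"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    chrom_len = {}
    for m in models:
        chrom_len[m.chrom] = max(chrom_len.get(m.chrom, 0), m.end + REF_FLANK)
    write_sam(reads, models, paths["sam"])
    write_vcf(snps_by_chrom, chrom_len, paths["vcf"], sample=sample)
    write_intron_bed(models, paths["bed"])
    write_truth(truth, paths["truth"])
    return paths


def write_sam(reads: Sequence[SimRead], models: Sequence[GeneModel], path: str) -> None:
    """Coordinate-sorted SAM v1.6 with the poly(A) length in the pt:f tag."""
    if not reads:
        raise ValueError("no reads to write")
    chrom_len: dict[str, int] = {}
    for m in models:
        chrom_len[m.chrom] = max(chrom_len.get(m.chrom, 0), m.end + REF_FLANK)
    chroms = sorted(chrom_len)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_len[c]} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in sorted(reads, key=lambda r: (tid[r.chrom], r.aln_start, r.read_id)):
            a = pysam.AlignedSegment()
            a.query_name = read.read_id
            a.flag = 16 if read.strand == "-" else 0
            a.reference_id = tid[read.chrom]
            a.reference_start = read.aln_start
            a.mapping_quality = 60
            a.cigarstring = "".join(f"{ln}{op}" for op, ln in read.cigar)
            a.query_sequence = read.seq
            a.set_tag(POLYA_TAG, float(read.polya_nt), value_type="f")
            out.write(a)


def write_vcf(
    snps_by_chrom: Mapping[str, Sequence[tuple[int, str, str]]],
    chrom_lengths: Mapping[str, int],
    path: str,
    sample: str = "sample1",
) -> None:
    """Phased heterozygous SNPs as VCF 4.2 with GT 0|1 (hap1 = REF)."""
    header = pysam.VariantHeader()
    for chrom in sorted(chrom_lengths):
        header.contigs.add(chrom, length=chrom_lengths[chrom])
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for chrom in sorted(snps_by_chrom):
            for pos, ref, alt in sorted(snps_by_chrom[chrom]):
                rec = vcf.new_record(
                    contig=chrom, start=pos, stop=pos + 1, alleles=(ref, alt),
                    id=f"{chrom}_{pos}",
                )
                rec.samples[sample]["GT"] = (0, 1)
                rec.samples[sample].phased = True
                vcf.write(rec)


def write_intron_bed(models: Sequence[GeneModel], path: str) -> None:
    """BED6 intron track; names encode gene and transcript-order index."""
    rows = []
    for m in models:
        for intron in m.introns:
            idx = m.intron_index(intron)
            rows.append((m.chrom, intron[0], intron[1], f"{m.gene_id}_intron{idx}", 0, m.strand))
    rows.sort()
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_truth(truth: pd.DataFrame, path: str) -> None:
    if truth.empty:
        raise ValueError("empty truth table")
    truth.sort_values("read_id").to_csv(path, sep="\t", index=False)


GENE_SPACING = 30_000  # genomic gap between simulated genes on one chromosome


def simulate_gene_set(
    gene_settings: Sequence[Mapping],
    seed: int,
    n_introns: int = 3,
    depth: float = 150.0,
    flip_prob: float = 0.05,
    unassignable_frac: float = 0.10,
) -> tuple[list[SimRead], pd.DataFrame, list[GeneModel], dict[str, list[tuple[int, str, str]]]]:
    """Simulate several well-separated genes on one chromosome.

    Each entry of ``gene_settings`` is a mapping of keyword overrides for
    :func:`make_allele_specs` (e.g. ``order_mixture_hap1``, ``polya_hap1``,
    ``end_sites_hap2``) plus optional ``gene_id``/``strand``. An empty
    mapping gives the null configuration (identical alleles).
    """
    reads: list[SimRead] = []
    truths = []
    models = []
    snps_by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for g, settings in enumerate(gene_settings):
        settings = dict(settings)
        gene_id = settings.pop("gene_id", f"gene{g}")
        strand = settings.pop("strand", "+")
        model = make_gene_model(
            n_introns, seed=seed + g, gene_id=gene_id, strand=strand,
            offset=10_000 + g * GENE_SPACING,
        )
        spec1, spec2, ref_seq, offset = make_allele_specs(
            model, seed=seed + g, depth=settings.pop("depth", depth), **settings
        )
        r, t = simulate_reads(
            model, (spec1, spec2), seed=seed + g, ref_seq=ref_seq, ref_offset=offset,
            flip_prob=flip_prob, unassignable_frac=unassignable_frac,
        )
        reads += r
        truths.append(t)
        models.append(model)
        snps_by_chrom.setdefault(model.chrom, []).extend(spec1.snps)
    return reads, pd.concat(truths, ignore_index=True), models, snps_by_chrom
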