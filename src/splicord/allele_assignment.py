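"""Assign reads to parental haplotypes from phased heterozygous SNPs.

A read is assigned to hap1 or hap2 when it covers at least two SNPs whose
bases match a haplotype and at least 75% of all its SNP observations agree
with that haplotype; otherwise it is undetermined. Bases matching neither
haplotype count toward the denominator of the agreement fraction but support
neither allele. Indels are never informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .intron_status import AlignedRead

log = logging.getLogger(__name__)

HAP1 = "hap1"
HAP2 = "hap2"
OTHER = "other"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class PhasedSNP:
    variant_id: str
    chrom: str
    pos: int  # 0-based
    hap1_base: str
    hap2_base: str


@dataclass(frozen=True)
class VariantObservation:
    read_id: str
    variant_id: str
    observed_allele: str  # hap1 | hap2 | other


@dataclass(frozen=True)
class AlleleCall:
    read_id: str
    allele: str  # hap1 | hap2 | undetermined
    n_informative: int
    agreement: float


def load_phased_snps(vcf_path: str) -> list[PhasedSNP]:
    """Phased heterozygous SNPs from a VCF; indels skipped with a warning."""
    snps = []
    with pysam.VariantFile(vcf_path) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            alts = rec.alts or ()
            if len(rec.ref) != 1 or any(len(a) != 1 for a in alts):
                log.warning("skipping indel at %s:%d", rec.chrom, rec.pos)
                continue
            gt = rec.samples[sample]
            alleles = gt.alleles
            if alleles is None or len(alleles) != 2 or not gt.phased:
                continue
            if alleles[0] == alleles[1]:
                continue  # homozygous: uninformative
            snps.append(
                PhasedSNP(
                    variant_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    hap1_base=alleles[0],
                    hap2_base=alleles[1],
                )
            )
    return snps


def extract_variant_observations(
    read: AlignedRead, snps: Sequence[PhasedSNP]
) -> list[VariantObservation]:
    """Which haplotype the read base matches at each M-covered SNP position.

    SNPs under N/D gaps or outside the alignment yield no observation.
    """
    if read.seq is None:
        raise ValueError(f"read {read.read_id} carries no sequence")
    by_pos = {snp.pos: snp for snp in snps if snp.chrom == read.chrom}
    obs = []
    rpos = read.aln_start
    qpos = 0
    for op, ln in read.cigar:
        if op in "M=X":
            for snp_pos in range(rpos, rpos + ln):
                snp = by_pos.get(snp_pos)
                if snp is None:
                    continue
                base = read.seq[qpos + (snp_pos - rpos)].upper()
                if base == snp.hap1_base.upper():
                    observed = HAP1
                elif base == snp.hap2_base.upper():
                    observed = HAP2
                else:
                    observed = OTHER
                obs.append(VariantObservation(read.read_id, snp.variant_id, observed))
            rpos += ln
            qpos += ln
        elif op in "DN":
            rpos += ln
        elif op in "IS":
            qpos += ln
        # H consumes neither
    return obs


def assign_allele(
    observations: Iterable[VariantObservation],
    min_informative: int = 2,
    min_agreement: float = 0.75,
    read_id: Optional[str] = None,
) -> AlleleCall:
    """Majority-haplotype call under the >=2-SNP / 75%-agreement rule.

    Agreement exactly at the threshold passes (only *less than* 75% fails).
    """
    obs = list(observations)
    if read_id is None:
        read_id = obs[0].read_id if obs else ""
    n1 = sum(1 for o in obs if o.observed_allele == HAP1)
    n2 = sum(1 for o in obs if o.observed_allele == HAP2)
    total = len(obs)
    n_informative = n1 + n2
    agreement = (max(n1, n2) / total) if total else 0.0
    if n_informative >= min_informative and agreement >= min_agreement and n1 != n2:
        allele = HAP1 if n1 > n2 else HAP2
    else:
        allele = UNDETERMINED
    return AlleleCall(read_id, allele, n_informative, agreement)


def assign_reads(
    reads: Iterable[AlignedRead],
    snps: Sequence[PhasedSNP],
    min_informative: int = 2,
    min_agreement: float = 0.75,
) -> pd.DataFrame:
    """Allele-call table (read_id, allele, n_informative, agreement)."""
    rows = []
    for read in reads:
        call = assign_allele(
            extract_variant_observations(read, snps),
            min_informative=min_informative,
            min_agreement=min_agreement,
            read_id=read.read_id,
        )
        rows.append((call.read_id, call.allele, call.n_informative, round(call.agreement, 6)))
    return pd.DataFrame(rows, columns=["read_id", "allele", "n_informative", "agreement"])
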