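"""Nascent-transcriptome construction for highly polymorphic loci.

Genome alignment of nascent HLA class I reads produces exon-skipping
artifacts around the tiny exon 6, so splicing analysis there is instead run
against an enumerated nascent transcriptome: for a gene with n introns,
every combination of retained introns (2^n isoforms, from fully spliced to
completely unspliced) is reconstructed from the haplotype genome sequence.
Reads re-aligned to these isoforms are quality-filtered on the percentage of
matching bases, 100 * (M + I - NM) / (M + I), where M and I are aligned and
inserted base counts and NM the edit distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .gene_model import GeneModel


@dataclass(frozen=True)
class NascentIsoform:
    gene_id: str
    haplotype: str
    retained_introns: tuple[int, ...]  # genomic-order intron indices
    name: str
    sequence: str


@dataclass(frozen=True)
class AlignmentStats:
    """Per-read alignment tallies: M aligned bases, I inserted bases, NM edit
    distance. NM can never exceed the aligned+inserted base count."""

    M: int
    I: int
    NM: int

    def __post_init__(self) -> None:
        if min(self.M, self.I, self.NM) < 0:
            raise ValueError("alignment tallies must be non-negative")
        if self.NM > self.M + self.I:
            raise ValueError("edit distance cannot exceed aligned + inserted bases")


def isoform_name(gene_id: str, haplotype: str, retained: tuple[int, ...], n_introns: int) -> str:
    """``gene_hap_bitmask`` with one bit per intron, 5'->3' genomic order."""
    bits = "".join("1" if i in retained else "0" for i in range(n_introns))
    return f"{gene_id}_{haplotype}_{bits}"


def decode_isoform_name(name: str) -> tuple[str, str, tuple[int, ...]]:
    gene_id, haplotype, bits = name.rsplit("_", 2)
    return gene_id, haplotype, tuple(i for i, b in enumerate(bits) if b == "1")


def enumerate_retained_intron_isoforms(
    model: GeneModel, haplotype_sequence: str, haplotype: str = "hap1",
    sequence_offset: int = 0,
) -> list[NascentIsoform]:
    """All 2^n retained-intron isoforms of one gene on one haplotype.

    ``haplotype_sequence`` must cover the gene span; ``sequence_offset`` is
    the genomic position of its first base. The empty retained set gives the
    concatenated exons; the full set gives the contiguous gene span.
    """
    if sequence_offset > model.start or len(haplotype_sequence) + sequence_offset < model.end:
        raise ValueError("haplotype sequence does not cover the gene span")

    def piece(interval: tuple[int, int]) -> str:
        s, e = interval
        return haplotype_sequence[s - sequence_offset : e - sequence_offset]

    isoforms = []
    n = model.n_introns
    for r in range(n + 1):
        for retained in itertools.combinations(range(n), r):
            parts = []
            for i, exon in enumerate(model.exons):
                parts.append(piece(exon))
                if i < n and i in retained:
                    parts.append(piece(model.introns[i]))
            isoforms.append(
                NascentIsoform(
                    gene_id=model.gene_id,
                    haplotype=haplotype,
                    retained_introns=retained,
                    name=isoform_name(model.gene_id, haplotype, retained, n),
                    sequence="".join(parts),
                )
            )
    return isoforms


def write_isoform_fasta(isoforms: list[NascentIsoform], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for iso in isoforms:
            fh.write(f">{iso.name}\n")
            for i in range(0, len(iso.sequence), width):
                fh.write(iso.sequence[i : i + width] + "\n")


def alignment_match_percent(stats: AlignmentStats) -> float:
    """100 * (M + I - NM) / (M + I); undefined (error) when M + I = 0."""
    denom = stats.M + stats.I
    if denom == 0:
        raise ValueError("match percentage undefined for an empty alignment")
    return 100.0 * (denom - stats.NM) / denom
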