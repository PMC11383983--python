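"""Gene models: ordered exon/intron structure for a single transcript.

All coordinates are 0-based half-open genomic intervals. Converters to/from
1-based formats (SAM, VCF) live at the IO boundary, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Minimum intron/exon length for which the +/- splice-site status windows
#: (50 nt total, 25 nt each side of a splice site) are meaningful.
MIN_FEATURE_LEN = 60


@dataclass(frozen=True)
class GeneModel:
    """One transcript's exon/intron structure, strand-aware.

    Exons are non-overlapping, sorted by genomic coordinate; introns are the
    gaps between consecutive exons. ``tss`` is the transcription start site:
    the leftmost position on '+' genes, the rightmost on '-' genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...] = field(init=False)
    tss: int = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) < 2:
            raise ValueError("a gene model needs at least two exons (one intron)")
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"empty or inverted exon [{s},{e})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 <= e0:
                raise ValueError("exons must be sorted and non-overlapping with gaps")
        introns = tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )
        for (s, e) in introns:
            if e - s < MIN_FEATURE_LEN:
                raise ValueError(
                    f"intron [{s},{e}) shorter than {MIN_FEATURE_LEN} nt; "
                    "splice-site windows would be degenerate"
                )
        object.__setattr__(self, "introns", introns)
        tss = self.exons[0][0] if self.strand == "+" else self.exons[-1][1]
        object.__setattr__(self, "tss", tss)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def intron_index(self, intron: tuple[int, int]) -> int:
        """Index of an intron in transcript (5'->3') order."""
        genomic_idx = self.introns.index(tuple(intron))
        if self.strand == "+":
            return genomic_idx
        return self.n_introns - 1 - genomic_idx

    def introns_transcript_order(self) -> tuple[tuple[int, int], ...]:
        """Introns ordered 5'->3' along the transcript."""
        return self.introns if self.strand == "+" else self.introns[::-1]


def make_gene_model(
    n_introns: int,
    exon_len: int = 200,
    intron_len: int = 1000,
    seed: int = 0,
    gene_id: str | None = None,
    chrom: str = "chr1",
    strand: str = "+",
    offset: int = 10_000,
) -> GeneModel:
    """Build a regular multi-intron gene for simulation.

    ``n_introns + 1`` exons of ``exon_len`` nt alternate with ``n_introns``
    introns of ``intron_len`` nt starting at ``offset``. Deterministic for a
    fixed seed (the seed shifts the gene start so distinct genes do not
    collide when several are placed on one chromosome).
    """
    if n_introns < 1:
        raise ValueError("n_introns must be >= 1")
    if exon_len < MIN_FEATURE_LEN or intron_len < MIN_FEATURE_LEN:
        raise ValueError(f"exon/intron lengths must be >= {MIN_FEATURE_LEN} nt")
    start = offset + (seed % 97) * 10
    exons = []
    pos = start
    for _ in range(n_introns + 1):
        exons.append((pos, pos + exon_len))
        pos += exon_len + intron_len
    exons[-1] = (exons[-1][0], exons[-1][0] + exon_len)
    if gene_id is None:
        gene_id = f"gene{seed}"
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=tuple(exons))
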