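"""Per-read intron excision status from spliced-alignment CIGAR strings.

For every (read, intron) pair the classifier decides whether the intron was
already excised (a CIGAR N gap matching the annotated intron), still present
(contiguous M coverage across the intron and its splice sites), skipped
(an N gap swallowing a splice-site region, e.g. around a skipped exon or an
alternative splice site), or undetermined. Reads spanning two or more introns
are further classified into splice-state classes (all unspliced / partially
spliced / all spliced).

Rules, in the order applied:

1. *excised* — an N op starts and ends within 50 nt of the intron's 5' and
   3' splice sites and its length is within 10% of the annotated intron size.
2. *not excised* — no N op near the intron, >50% M coverage of the 50-nt
   window around each splice site, and >75% M coverage of the part of the
   intron the read maps across. A read starting inside the intron (no
   coverage of the 5' splice site) qualifies if the 3'-side criteria hold.
3. *skipped* — an N op overlaps more than half of the 50-nt window around
   the 5' and/or 3' splice site while the intron portion inside the gap is
   within 10% of the annotated size.
4. *undetermined* — anything else.

The 50-nt splice-site window is centred on the splice site (25 nt each side).
Only M ops count as coverage. Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

EXCISED = "excised"
NOT_EXCISED = "not_excised"
SKIPPED = "skipped"
UNDETERMINED = "undetermined"

ALL_SPLICED = "all_spliced"
ALL_UNSPLICED = "all_unspliced"
PARTIALLY_SPLICED = "partially_spliced"
NOT_CLASSIFIABLE = "not_classifiable"

_REF_OPS = frozenset("MDN=X")
_QUERY_OPS = frozenset("MIS=X")


@dataclass(frozen=True)
class AlignedRead:
    """Minimal spliced alignment: what the classifier and allele caller need."""

    read_id: str
    chrom: str
    strand: str
    aln_start: int
    cigar: tuple[tuple[str, int], ...]
    seq: Optional[str] = None
    polya_nt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.aln_start < 0:
            raise ValueError("aln_start must be >= 0")
        for op, ln in self.cigar:
            if op not in "MIDNSH=X":
                raise ValueError(f"unsupported CIGAR op {op!r}")
            if ln <= 0:
                raise ValueError("CIGAR op lengths must be positive")

    @property
    def ref_end(self) -> int:
        return self.aln_start + sum(ln for op, ln in self.cigar if op in _REF_OPS)

    def ref_blocks(self) -> list[tuple[str, int, int]]:
        """Reference-consuming ops as (op, ref_start, ref_end)."""
        blocks = []
        pos = self.aln_start
        for op, ln in self.cigar:
            if op in _REF_OPS:
                blocks.append(("M" if op in "=X" else op, pos, pos + ln))
                pos += ln
        return blocks


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    if num:
        raise ValueError(f"trailing digits in CIGAR {cigar!r}")
    return tuple(out)


def from_pysam(aln) -> AlignedRead:
    """Convert a pysam.AlignedSegment (with optional poly(A) tag)."""
    polya = None
    for tag in ("pt", "pa"):
        if aln.has_tag(tag):
            polya = float(aln.get_tag(tag))
            break
    return AlignedRead(
        read_id=aln.query_name,
        chrom=aln.reference_name,
        strand="-" if aln.is_reverse else "+",
        aln_start=aln.reference_start,
        cigar=tuple((c, l) for c, l in ((("MIDNSHP=XB"[op]), ln) for op, ln in aln.cigartuples)),
        seq=aln.query_sequence,
        polya_nt=polya,
    )


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _coverage(blocks: Sequence[tuple[str, int, int]], start: int, end: int, op: str = "M") -> int:
    return sum(_overlap(s, e, start, end) for o, s, e in blocks if o == op)


def classify_intron(
    read: AlignedRead,
    intron: tuple[int, int],
    strand: str | None = None,
    ss_window: int = 50,
    size_tol: float = 0.10,
) -> Optional[str]:
    """Excision status of one intron in one read, or None if the read does
    not overlap the intron's evaluation window (pair excluded, no call).

    ``strand`` is the gene's strand (defaults to the read's); it decides
    which intron boundary is the 5' splice site for the start-within-intron
    rule. ``ss_window`` is the total window width centred on each splice site.
    """
    s, e = intron
    if e <= s:
        raise ValueError(f"empty intron [{s},{e})")
    strand = strand or read.strand
    half = ss_window // 2
    r0, r1 = read.aln_start, read.ref_end
    if _overlap(r0, r1, s - half, e + half) == 0:
        return None

    blocks = read.ref_blocks()
    intron_len = e - s
    n_blocks = [(bs, be) for op, bs, be in blocks if op == "N"]

    # 1) excised: an N gap matching the annotated intron
    for ns, ne in sorted(n_blocks, key=lambda b: -_overlap(b[0], b[1], s, e)):
        if (
            abs(ns - s) <= ss_window
            and abs(ne - e) <= ss_window
            and abs((ne - ns) - intron_len) <= size_tol * intron_len
        ):
            return EXCISED

    donor = s if strand == "+" else e
    acceptor = e if strand == "+" else s
    donor_win = (donor - half, donor + half)
    acceptor_win = (acceptor - half, acceptor + half)

    # 2) not excised: no N near the intron, M across splice sites and body
    no_n = all(_overlap(ns, ne, s - half, e + half) == 0 for ns, ne in n_blocks)
    if no_n:
        body0, body1 = max(s, r0), min(e, r1)
        body_len = max(0, body1 - body0)
        body_ok = body_len == 0 or _coverage(blocks, body0, body1) > 0.75 * body_len
        donor_cov = _coverage(blocks, *donor_win)
        acceptor_cov = _coverage(blocks, *acceptor_win)
        if donor_cov > 0.5 * ss_window and acceptor_cov > 0.5 * ss_window and body_ok:
            return NOT_EXCISED
        # read starts (transcript 5' end) inside the intron: 3'-side rules only
        t5 = r0 if strand == "+" else r1
        starts_inside = s < t5 < e if strand == "+" else s < t5 <= e
        if starts_inside and donor_cov == 0 and acceptor_cov > 0.5 * ss_window and body_ok:
            return NOT_EXCISED

    # 3) skipped: N swallowing a splice-site region, intron-sized inside
    for ns, ne in sorted(n_blocks, key=lambda b: -_overlap(b[0], b[1], s, e)):
        eats_donor = _overlap(ns, ne, *donor_win) > 0.5 * ss_window
        eats_acceptor = _overlap(ns, ne, *acceptor_win) > 0.5 * ss_window
        inside = _overlap(ns, ne, s, e)
        if (eats_donor or eats_acceptor) and abs(inside - intron_len) <= size_tol * intron_len:
            return SKIPPED

    return UNDETERMINED


def classify_read_splice_state(statuses: Iterable[str]) -> str:
    """Splice-state class of a read spanning >= 2 introns.

    Only excised / not-excised statuses decide the class; skipped and
    undetermined introns are ignored, and a read with none of the former is
    not classifiable.
    """
    statuses = list(statuses)
    if len(statuses) < 2:
        raise ValueError("splice-state classes are defined for reads spanning >= 2 introns")
    informative = [st for st in statuses if st in (EXCISED, NOT_EXCISED)]
    if not informative:
        return NOT_CLASSIFIABLE
    has_exc = EXCISED in informative
    has_ret = NOT_EXCISED in informative
    if has_exc and has_ret:
        return PARTIALLY_SPLICED
    return ALL_SPLICED if has_exc else ALL_UNSPLICED


def classify_reads(
    reads: Iterable[AlignedRead],
    introns: Sequence[tuple[str, int, int, str, str, int]],
    ss_window: int = 50,
    size_tol: float = 0.10,
) -> pd.DataFrame:
    """Status table for many reads against an intron annotation.

    ``introns`` rows are (chrom, start, end, gene_id, strand, intron_index)
    with intron_index in transcript 5'->3' order. Returns a long DataFrame
    (read_id, gene_id, intron_index, status); pairs without a call are absent.
    Candidate (read, intron) pairs come from an interval index so runtime
    scales with overlaps, not with annotation size.
    """
    half = ss_window // 2
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e, gene, strand, idx in introns:
        trees.setdefault(chrom, IntervalTree()).addi(s - half, e + half, (s, e, gene, strand, idx))
    rows = []
    for read in reads:
        tree = trees.get(read.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(read.aln_start, read.ref_end)):
            s, e, gene, strand, idx = hit.data
            status = classify_intron(read, (s, e), strand=strand, ss_window=ss_window, size_tol=size_tol)
            if status is not None:
                rows.append((read.read_id, gene, idx, status))
    return pd.DataFrame(rows, columns=["read_id", "gene_id", "intron_index", "status"])


def splice_state_table(status_df: pd.DataFrame) -> pd.DataFrame:
    """Per (read, gene) splice-state class for reads spanning >= 2 introns."""
    rows = []
    for (read_id, gene), grp in status_df.groupby(["read_id", "gene_id"], sort=True):
        if len(grp) < 2:
            continue
        rows.append((read_id, gene, classify_read_splice_state(grp["status"])))
    return pd.DataFrame(rows, columns=["read_id", "gene_id", "splice_state"])
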