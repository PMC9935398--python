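"""Candidate poly(A) tail derivation, classification, and read filtering.

The candidate tail of a mapped long read is its terminal soft clip, taken in
transcript orientation: the 3′ clip for + strand reads, the reverse
complement of the 5′ clip for − strand reads.  A candidate is accepted as a
genuine tail (``TRUE``) unless its T/C/G content is uniformly high
(``HIGH_TCG``: each of T, C, G makes up at least 10% of the clip) or its
residue-transition score exceeds 12 (``FALSE_score_12+``), which flags
clips that look like unaligned mRNA body rather than a tail.

Also implemented here: the poly(A)+ read filter (pass count >= 10 and tail
length >= 1), UMI-based PCR-duplicate removal, the last-exon restriction
used for fragmentation-prone libraries, FLAM-seq GI-tail (G-run) parsing,
and a toy overlap-based read-to-gene assigner for use when no external
assignment table is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

from .io_formats import AlignedRead, GeneModel, TailRecord

TRUE = "TRUE"
HIGH_TCG = "HIGH_TCG"
FALSE_SCORE_12PLUS = "FALSE_score_12+"

#: minimum proportion of each of T, C and G for the HIGH_TCG call
HIGH_TCG_MIN_PROP = 0.1
#: transition-score cutoff; strictly greater scores are rejected
MAX_TRANSITION_SCORE = 12

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TailClassification:
    """Label plus the statistics the classification was based on."""

    label: str
    transition_score: int
    prop_t: float
    prop_c: float
    prop_g: float


def extract_candidate_tail(read: AlignedRead) -> str:
    """Return the candidate tail of a read, 5′→3′ in transcript orientation.

    + strand reads contribute their 3′ soft clip as-is; − strand reads
    contribute the reverse complement of their 5′ (low-coordinate) soft clip,
    so a poly(A) tail always reads as an A-rich string.  An empty string is a
    valid 0-nt tail.
    """
    if read.strand == "+":
        return read.clip3.upper()
    return reverse_complement(read.clip5.upper())


def extract_tail_qualities(read: AlignedRead) -> Optional[Sequence[int]]:
    """Per-base qualities of the candidate tail, in tail orientation."""
    if read.strand == "+":
        return read.clip3_qualities
    if read.clip5_qualities is None:
        return None
    return list(read.clip5_qualities)[::-1]


def transition_score(seq: str) -> int:
    """Number of adjacent unequal residue pairs, scanned 5′→3′.

    A homopolymer scores 0; every residue change adds 1.  Sequences of
    length <= 1 score 0.
    """
    return sum(a != b for a, b in zip(seq, seq[1:]))


def classify_tail(seq: str) -> TailClassification:
    """Classify a candidate tail as TRUE, HIGH_TCG or FALSE_score_12+.

    The HIGH_TCG test is applied first: if T, C and G each make up at least
    10% of the clip the read is rejected as high-complexity.  Otherwise a
    transition score above 12 rejects it as FALSE_score_12+.  Everything
    else, including the empty (0-nt) tail, is TRUE.  Proportions are
    computed over non-N bases; N is a no-call.
    """
    seq = seq.upper()
    denom = len(seq) - seq.count("N")
    if denom > 0:
        prop_t = seq.count("T") / denom
        prop_c = seq.count("C") / denom
        prop_g = seq.count("G") / denom
    else:
        prop_t = prop_c = prop_g = 0.0
    score = transition_score(seq)
    if denom > 0 and min(prop_t, prop_c, prop_g) >= HIGH_TCG_MIN_PROP:
        label = HIGH_TCG
    elif score > MAX_TRANSITION_SCORE:
        label = FALSE_SCORE_12PLUS
    else:
        label = TRUE
    return TailClassification(label, score, prop_t, prop_c, prop_g)


def filter_polya_plus(
    records: Iterable[TailRecord], min_pass: int = 10
) -> list[TailRecord]:
    """Keep poly(A)+ records: pass count >= ``min_pass`` and tail >= 1 nt.

    Tail records are only ever built from TRUE-classified candidate tails,
    so the classification requirement is implied by construction.  Records
    with unknown pass count are dropped.  The filter is idempotent and the
    output is a subset of the input.
    """
    return [
        r
        for r in records
        if r.pass_count is not None
        and r.pass_count >= min_pass
        and len(r.tail_seq) >= 1
    ]


class DedupResult(NamedTuple):
    records: list
    n_missing_umi: int


def dedup_umi(records: Iterable, gene_of: Optional[dict] = None) -> DedupResult:
    """Collapse PCR duplicates: one record per (barcode, UMI, gene) key.

    Among duplicates the record with the highest pass count is kept (the
    consensus of more passes is the most accurate); ties break to the
    lexicographically smallest read id.  Records without a UMI cannot be
    deduplicated and pass through unchanged; their number is reported.
    Works on any records exposing ``barcode``, ``umi``, ``pass_count`` and
    ``read_id`` (both :class:`AlignedRead` and :class:`TailRecord` qualify,
    the latter through ``gene_of`` = None using its own ``gene_id``).
    """
    best: dict[tuple, object] = {}
    passthrough: list = []
    order: list[tuple] = []
    for rec in records:
        umi = getattr(rec, "umi", None)
        if not umi:
            passthrough.append(rec)
            continue
        if gene_of is not None:
            gene = gene_of.get(rec.read_id)
        else:
            gene = getattr(rec, "gene_id", None)
        key = (rec.barcode, umi, gene)
        incumbent = best.get(key)
        if incumbent is None:
            best[key] = rec
            order.append(key)
        elif _dedup_rank(rec) > _dedup_rank(incumbent):
            best[key] = rec
    kept = [best[k] for k in order] + passthrough
    return DedupResult(kept, len(passthrough))


def _dedup_rank(rec) -> tuple:
    pc = rec.pass_count if rec.pass_count is not None else -1
    return (pc, _NegStr(rec.read_id))


class _NegStr(str):
    """String whose ordering is reversed, for 'smallest read id wins' in a max."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def read_end_on_genome(read: AlignedRead, strand: str) -> int:
    """Genomic position of the read's polyadenylation site (3′-most aligned base)."""
    return read.aln_end if strand == "+" else read.aln_start


def last_exon_filter(read: AlignedRead, gene: GeneModel) -> bool:
    """True iff the read's polyadenylation site lies within the gene's last exon."""
    end = read_end_on_genome(read, gene.strand)
    lo, hi = gene.last_exon
    return lo <= end <= hi


# -- FLAM-seq GI-tail parsing ------------------------------------------------

DISCARD = None
_MIN_G_RUN = 7
_MAX_G_STRIP = 17


def flam_split_gi_tail(raw_3prime_segment: str) -> Optional[str]:
    """Strip the GI-tailing G-run from a FLAM-seq read 3′ segment.

    ``raw_3prime_segment`` is the read portion ending immediately before the
    UMI/barcode.  Library preparation appends ~9 guanosines after the tail;
    a trailing G-run of fewer than 7 means the read structure is unreliable
    and the read is discarded (returns ``None``).  Runs of 7-16 G are
    removed entirely; for runs of 17 or more exactly the 3′-most 17 G are
    removed and any surplus G (possible genuine tail guanylation) retained.
    """
    seg = raw_3prime_segment
    g = len(seg) - len(seg.rstrip("G"))
    if g < _MIN_G_RUN:
        return DISCARD
    if g <= 16:
        return seg[: len(seg) - g]
    return seg[: len(seg) - _MAX_G_STRIP]


def assign_gene(read: AlignedRead, genes: Iterable[GeneModel]) -> Optional[str]:
    """Toy overlap assigner: the unique same-strand gene containing the read.

    A gene matches if it shares chromosome and strand with the read and its
    span contains the read's polyadenylation site or overlaps the aligned
    interval.  Reads matching zero or more than one gene get ``None``.
    Intended as plumbing for when no featureCounts-style table is supplied.
    """
    hits = []
    for gene in genes:
        if gene.chrom != read.chrom or gene.strand != read.strand:
            continue
        lo, hi = gene.gene_span
        end = read_end_on_genome(read, gene.strand)
        overlaps = read.aln_start <= hi and read.aln_end >= lo
        if lo <= end <= hi or overlaps:
            hits.append(gene.gene_id)
    return hits[0] if len(hits) == 1 else None
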