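"""Polyadenylation-site calling and PIT/PDI read classification.

Sites are called per gene from the 3′-end positions of poly(A)+ reads by a
greedy peak finder: among observed end positions at least 20 nt away from
every already-called site, the position supported by the most read ends
within +-5 nt is called, provided that support reaches 10 reads; the loop
repeats until no position qualifies.  Reads are then classified against a
catalog (possibly from a reference sample, mirroring the use of a
germinal-vesicle catalog for later stages): a read ending within 5 nt of a
site is a polyadenylated intact transcript (PIT); a read ending more than
5 nt 5′-upstream of at least one site is a polyadenylated degradation
intermediate (PDI); everything else is unassigned and excluded from PDI
proportions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io_formats import PAS_CATALOG_COLUMNS, AlignedRead, GeneModel

PIT = "PIT"
PDI = "PDI"
UNASSIGNED = "UNASSIGNED"

DEFAULT_MIN_SUPPORT = 10
DEFAULT_WINDOW = 5
DEFAULT_MIN_SEPARATION = 20


@dataclass(frozen=True)
class PasSite:
    position: int
    support: int
    label: str = "other"  # pPAS / dPAS / other


@dataclass
class GenePas:
    gene_id: str
    chrom: str
    strand: str
    sites: list[PasSite] = field(default_factory=list)

    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.sites]


@dataclass
class PASCatalog:
    """Called polyadenylation sites per gene."""

    genes: dict[str, GenePas] = field(default_factory=dict)

    def sites_for(self, gene_id: str) -> list[PasSite]:
        entry = self.genes.get(gene_id)
        return entry.sites if entry else []

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "position": s.position,
                "support": s.support,
                "label": s.label,
            }
            for g in self.genes.values()
            for s in g.sites
        ]
        return pd.DataFrame(rows, columns=PAS_CATALOG_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PASCatalog":
        cat = cls()
        for gid, sub in frame.groupby("gene_id", sort=False):
            first = sub.iloc[0]
            cat.genes[str(gid)] = GenePas(
                gene_id=str(gid),
                chrom=str(first["chrom"]),
                strand=str(first["strand"]),
                sites=[
                    PasSite(int(r.position), int(r.support), str(r.label))
                    for r in sub.itertuples()
                ],
            )
        return cat


@dataclass(frozen=True)
class ReadEndAssignment:
    read_id: str
    gene_id: str
    end_position: int
    category: str  # PIT / PDI / UNASSIGNED
    matched_pas: Optional[int] = None
    end_region: str = "other"  # PAS_match / UTR3 / CDS / other


def read_end_position(read: AlignedRead, strand: str) -> int:
    """The read's polyadenylation site: 3′-most aligned base in transcript orientation."""
    return read.aln_end if strand == "+" else read.aln_start


def call_pas(
    end_positions: Iterable[int],
    min_support: int = DEFAULT_MIN_SUPPORT,
    window: int = DEFAULT_WINDOW,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    strand: str = "+",
) -> list[PasSite]:
    """Greedy per-gene PAS calling from a multiset of read-end coordinates.

    Candidate sites are the observed end positions themselves (a position
    with no exact read end is always dominated by a nearby observed end).
    Each round considers candidates farther than ``min_separation`` nt
    (|delta| <= min_separation excluded) from every called site, scores each
    by the number of read ends within ``window`` nt inclusive, and calls the
    best-supported one if its support reaches ``min_support``.  Support ties
    break to the candidate with more exact-position reads, then to the
    5′-most coordinate (smallest on +, largest on −).  Reads are never
    consumed between rounds.  Returns sites in call order.
    """
    counts = Counter(end_positions)
    if not counts:
        return []
    positions = sorted(counts)
    support = {
        p: sum(counts[q] for q in counts if abs(q - p) <= window) for p in positions
    }
    called: list[PasSite] = []
    while True:
        best = None
        best_key = None
        for p in positions:
            if any(abs(p - s.position) <= min_separation for s in called):
                continue
            # 5'-most preference: smallest coordinate on +, largest on −
            tiebreak = -p if strand == "+" else p
            key = (support[p], counts[p], tiebreak)
            if best_key is None or key > best_key:
                best, best_key = p, key
        if best is None or support[best] < min_support:
            break
        called.append(PasSite(best, support[best]))
    return called


def label_proximal_distal(sites: Sequence[PasSite], strand: str) -> list[PasSite]:
    """Label pPAS/dPAS for a gene with exactly two sites.

    The site nearer the transcription start (smaller coordinate on +,
    larger on −) is proximal.  Genes with any other site count are returned
    with labels untouched.
    """
    if len(sites) != 2:
        return list(sites)
    ordered = sorted(sites, key=lambda s: s.position, reverse=(strand == "-"))
    return sorted(
        [
            PasSite(ordered[0].position, ordered[0].support, "pPAS"),
            PasSite(ordered[1].position, ordered[1].support, "dPAS"),
        ],
        key=lambda s: s.position,
    )


def build_catalog(
    ends_by_gene: Mapping[str, Iterable[int]],
    genes: Mapping[str, GeneModel],
    min_support: int = DEFAULT_MIN_SUPPORT,
    window: int = DEFAULT_WINDOW,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> PASCatalog:
    """Call PAS for every gene with poly(A)+ read ends and label 2-site genes."""
    cat = PASCatalog()
    for gid in sorted(ends_by_gene):
        gene = genes[gid]
        sites = call_pas(
            ends_by_gene[gid],
            min_support=min_support,
            window=window,
            min_separation=min_separation,
            strand=gene.strand,
        )
        if not sites:
            continue
        sites = label_proximal_distal(sites, gene.strand)
        cat.genes[gid] = GenePas(gid, gene.chrom, gene.strand, list(sites))
    return cat


def classify_reads(
    read_ends: Iterable[tuple[str, int]],
    sites: Sequence[PasSite],
    gene: GeneModel,
    window: int = DEFAULT_WINDOW,
) -> list[ReadEndAssignment]:
    """Classify each (read_id, end) of a gene as PIT, PDI or UNASSIGNED.

    A read is a PIT when its end is within ``window`` nt (inclusive) of a
    site; the nearest site wins and exact distance ties go to the 5′-most
    site.  Otherwise it is a PDI when the end lies more than ``window`` nt
    5′-upstream of at least one site (end < site − window on +, end >
    site + window on −).  Remaining reads — and all reads of genes with no
    catalog entry — are UNASSIGNED.  PDI ends are annotated with the region
    they fall in: CDS, 3′-UTR (within the last exon downstream of the CDS
    end), or other.
    """
    plus = gene.strand == "+"
    out: list[ReadEndAssignment] = []
    for read_id, end in read_ends:
        if not sites:
            out.append(ReadEndAssignment(read_id, gene.gene_id, end, UNASSIGNED))
            continue
        near = [s for s in sites if abs(end - s.position) <= window]
        if near:
            best = min(
                near,
                key=lambda s: (
                    abs(end - s.position),
                    s.position if plus else -s.position,
                ),
            )
            out.append(
                ReadEndAssignment(
                    read_id, gene.gene_id, end, PIT,
                    matched_pas=best.position, end_region="PAS_match",
                )
            )
            continue
        upstream = any(
            end < s.position - window if plus else end > s.position + window
            for s in sites
        )
        if upstream:
            out.append(
                ReadEndAssignment(
                    read_id, gene.gene_id, end, PDI,
                    end_region=_pdi_region(end, gene),
                )
            )
        else:
            out.append(ReadEndAssignment(read_id, gene.gene_id, end, UNASSIGNED))
    return out


def _pdi_region(end: int, gene: GeneModel) -> str:
    if gene.in_cds(end):
        return "CDS"
    lo, hi = gene.last_exon
    if lo <= end <= hi:
        cds_end = gene.cds_end
        if cds_end is None:
            return "UTR3"
        downstream = end > cds_end if gene.strand == "+" else end < cds_end
        if downstream:
            return "UTR3"
    return "other"
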