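"""End-to-end orchestration: SAM -> tail records -> PAS catalog -> PIT/PDI.

Thin glue over the library modules, shared by the command-line interface
and by scripted analyses.  The per-read flow mirrors the library protocols:
gene assignment (table or overlap), optional UMI deduplication and
last-exon restriction (UMI-tagged libraries), candidate-tail extraction and
classification, then annotation of TRUE tails into the 13-column records.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from . import pas_pdi, summaries, tail_extract, tail_stats
from .io_formats import AlignedRead, GeneModel, TailRecord, read_alignments
from .pas_pdi import PASCatalog, ReadEndAssignment
from .tail_extract import TRUE


class _GeneIndex:
    """Sorted-span lookup of candidate genes per (chrom, strand)."""

    def __init__(self, genes: Mapping[str, GeneModel]):
        self._by_key: dict[tuple[str, str], tuple[list[int], list[GeneModel]]] = {}
        self._max_span: dict[tuple[str, str], int] = {}
        buckets: dict[tuple[str, str], list[GeneModel]] = {}
        for gene in genes.values():
            buckets.setdefault((gene.chrom, gene.strand), []).append(gene)
        for key, items in buckets.items():
            items.sort(key=lambda g: g.gene_span[0])
            self._by_key[key] = ([g.gene_span[0] for g in items], items)
            self._max_span[key] = max(
                g.gene_span[1] - g.gene_span[0] + 1 for g in items
            )

    def candidates(self, read: AlignedRead) -> list[GeneModel]:
        key = (read.chrom, read.strand)
        if key not in self._by_key:
            return []
        starts, items = self._by_key[key]
        hi = bisect_right(starts, read.aln_end)
        lo_bound = read.aln_start - self._max_span[key]
        out = []
        i = hi - 1
        while i >= 0 and starts[i] >= lo_bound:
            out.append(items[i])
            i -= 1
        return out


@dataclass
class ExtractionResult:
    """TRUE-classified tail records plus per-read end positions and tallies."""

    records: list[TailRecord]
    ends: dict[str, tuple[str, int]]  # read_id -> (gene_id, genomic end)
    label_counts: dict[str, int] = field(default_factory=dict)
    n_unassigned_reads: int = 0
    n_missing_umi: int = 0


def extract_tails(
    sam_path,
    genes: Mapping[str, GeneModel],
    assignment: Optional[Mapping[str, str]] = None,
    mode: str = "paiso1",
) -> ExtractionResult:
    """Run gene assignment, filtering and tail classification over a SAM/BAM.

    ``mode='paiso2'`` additionally deduplicates reads by (barcode, UMI,
    gene) and keeps only reads whose polyadenylation site falls in the last
    exon of their gene.  Reads that cannot be assigned to a unique gene are
    dropped (counted).
    """
    if mode not in ("paiso1", "paiso2"):
        raise ValueError(f"unknown mode {mode!r}")
    index = _GeneIndex(genes)
    assigned: list[tuple[AlignedRead, GeneModel]] = []
    n_unassigned = 0
    for read in read_alignments(sam_path):
        gid = None
        if assignment is not None:
            gid = assignment.get(read.read_id)
            if gid is not None and gid not in genes:
                gid = None
        else:
            gid = tail_extract.assign_gene(read, index.candidates(read))
        if gid is None:
            n_unassigned += 1
            continue
        assigned.append((read, genes[gid]))

    n_missing_umi = 0
    if mode == "paiso2":
        gene_of = {read.read_id: gene.gene_id for read, gene in assigned}
        gene_by_read = {read.read_id: gene for read, gene in assigned}
        result = tail_extract.dedup_umi([r for r, _ in assigned], gene_of=gene_of)
        n_missing_umi = result.n_missing_umi
        assigned = [(r, gene_by_read[r.read_id]) for r in result.records]
        assigned = [
            (r, g) for r, g in assigned if tail_extract.last_exon_filter(r, g)
        ]

    records: list[TailRecord] = []
    ends: dict[str, tuple[str, int]] = {}
    label_counts: dict[str, int] = {}
    for read, gene in assigned:
        tail = tail_extract.extract_candidate_tail(read)
        cls = tail_extract.classify_tail(tail)
        label_counts[cls.label] = label_counts.get(cls.label, 0) + 1
        if cls.label != TRUE:
            continue
        quals = tail_extract.extract_tail_qualities(read)
        records.append(
            tail_stats.annotate_tail(
                read.read_id,
                gene.gene_id,
                read.barcode,
                read.pass_count if read.pass_count is not None else -1,
                tail,
                quals,
            )
        )
        ends[read.read_id] = (
            gene.gene_id,
            pas_pdi.read_end_position(read, gene.strand),
        )
    return ExtractionResult(records, ends, label_counts, n_unassigned, n_missing_umi)


def call_catalog(
    polya_records: Iterable[TailRecord],
    ends: Mapping[str, tuple[str, int]],
    genes: Mapping[str, GeneModel],
    min_support: int = pas_pdi.DEFAULT_MIN_SUPPORT,
) -> PASCatalog:
    """Call the PAS catalog from the 3′ ends of poly(A)+ records."""
    ends_by_gene: dict[str, list[int]] = {}
    for rec in polya_records:
        hit = ends.get(rec.read_id)
        if hit is None:
            continue
        gid, end = hit
        ends_by_gene.setdefault(gid, []).append(end)
    return pas_pdi.build_catalog(ends_by_gene, genes, min_support=min_support)


def classify_sample(
    polya_records: Iterable[TailRecord],
    ends: Mapping[str, tuple[str, int]],
    catalog: PASCatalog,
    genes: Mapping[str, GeneModel],
) -> list[ReadEndAssignment]:
    """Classify every poly(A)+ read as PIT / PDI / UNASSIGNED against a catalog."""
    by_gene: dict[str, list[tuple[str, int]]] = {}
    for rec in polya_records:
        hit = ends.get(rec.read_id)
        if hit is None:
            continue
        gid, end = hit
        by_gene.setdefault(gid, []).append((rec.read_id, end))
    out: list[ReadEndAssignment] = []
    for gid in sorted(by_gene):
        out.extend(
            pas_pdi.classify_reads(by_gene[gid], catalog.sites_for(gid), genes[gid])
        )
    return out


def analyze_sample(
    sam_path,
    genes: Mapping[str, GeneModel],
    assignment: Optional[Mapping[str, str]] = None,
    mode: str = "paiso1",
    min_pass: int = 10,
    pas_reference: Optional[PASCatalog] = None,
) -> dict:
    """Full single-sample analysis; returns records, catalog, assignments, summaries."""
    extraction = extract_tails(sam_path, genes, assignment=assignment, mode=mode)
    polya = tail_extract.filter_polya_plus(extraction.records, min_pass=min_pass)
    catalog = pas_reference or call_catalog(polya, extraction.ends, genes)
    assignments = classify_sample(polya, extraction.ends, catalog, genes)
    lengths = [len(r.tail_seq) for r in polya]
    return {
        "extraction": extraction,
        "polya_records": polya,
        "catalog": catalog,
        "assignments": assignments,
        "pdi_proportion": summaries.pdi_proportion(assignments),
        "u_fraction": summaries.transcript_nona_proportion(polya, "T"),
        "median_tail_length": (
            summaries.tail_length_histogram(lengths)[1] if lengths else float("nan")
        ),
    }
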