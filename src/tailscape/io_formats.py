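"""Readers and writers for the external formats the tail pipeline touches.

The pipeline consumes aligned long reads (SAM/BAM with the poly(A) tail left
as a terminal soft clip), a GTF gene annotation, and optionally a
featureCounts-style read-to-gene assignment table.  It emits a fixed
13-column per-read tail table (the ``polyA_note`` layout) and a
polyadenylation-site catalog CSV.  Genomic coordinates are 1-based inclusive
throughout, matching the SAM convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import gffutils
import pandas as pd
import pysam

#: samtools ``-F 3844``: unmapped, secondary, QC-fail, duplicate, supplementary.
EXCLUDE_FLAGS = 0x4 | 0x100 | 0x200 | 0x400 | 0x800

_SOFT_CLIP = 4  # CIGAR operation code


@dataclass
class AlignedRead:
    """One mapped long read with terminal soft clips and per-read metadata.

    ``clip5``/``clip3`` are the soft-clipped sequences at the low- and
    high-coordinate ends of the alignment, exactly as stored in the SAM SEQ
    field (reference orientation).  For a − strand read the poly(A) tail
    therefore appears as a leading T-run in ``clip5``.
    """

    read_id: str
    barcode: str
    pass_count: Optional[int]
    chrom: str
    strand: str
    aln_start: int
    aln_end: int
    clip5: str = ""
    clip3: str = ""
    umi: Optional[str] = None
    is_supplementary: bool = False
    clip5_qualities: Optional[Sequence[int]] = None
    clip3_qualities: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.aln_start > self.aln_end:
            raise ValueError(
                f"aln_start {self.aln_start} > aln_end {self.aln_end} for {self.read_id}"
            )


@dataclass
class GeneModel:
    """A gene with exons ordered 5′→3′ in transcript orientation."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: Optional[list[tuple[int, int]]] = None
    gene_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        # store exons sorted by genomic coordinate; transcript order derives
        # from strand
        self.exons = sorted(self.exons)
        if self.gene_span is None:
            self.gene_span = (self.exons[0][0], self.exons[-1][1])

    @property
    def last_exon(self) -> tuple[int, int]:
        """The 3′-most exon in transcript orientation."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def cds_end(self) -> Optional[int]:
        """Genomic coordinate of the CDS stop in transcript orientation."""
        if not self.cds:
            return None
        return max(e for _, e in self.cds) if self.strand == "+" else min(
            s for s, _ in self.cds
        )

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds or [])


@dataclass
class TailRecord:
    """One row of the 13-column per-read poly(A)-tail annotation table.

    Column order on disk: barcode, read id, gene id, pass number, the literal
    "1", counts of A/T/C/G, the non-A count, the literal "0", the tail
    sequence, and the mean base quality of the tail.  N bases are retained in
    ``tail_seq`` but contribute to none of the counts.
    """

    barcode: str
    read_id: str
    gene_id: str
    pass_count: int
    count_a: int
    count_t: int
    count_c: int
    count_g: int
    count_nona: int
    tail_seq: str
    mean_tail_qv: float = 0.0

    @property
    def tail_length(self) -> int:
        return len(self.tail_seq)

    def validate(self) -> None:
        seq = self.tail_seq
        for name, base, n in (
            ("count_a", "A", self.count_a),
            ("count_t", "T", self.count_t),
            ("count_c", "C", self.count_c),
            ("count_g", "G", self.count_g),
        ):
            if n != seq.count(base):
                raise ValueError(
                    f"{self.read_id}: {name}={n} but tail has {seq.count(base)}"
                )
        if self.count_nona != self.count_t + self.count_c + self.count_g:
            raise ValueError(f"{self.read_id}: non-A count inconsistent")
        if any(n < 0 for n in (self.count_a, self.count_t, self.count_c, self.count_g)):
            raise ValueError(f"{self.read_id}: negative count")


class AlignmentParseError(ValueError):
    """A SAM/BAM record could not be interpreted; carries the read id."""


def _parse_read_name(name: str) -> tuple[str, Optional[str], Optional[int]]:
    """Split a ``ccs:barcode:pass`` read name; returns (ccs id, barcode, pass)."""
    parts = name.rsplit(":", 2)
    if len(parts) == 3:
        try:
            return parts[0], parts[1], int(parts[2])
        except ValueError:
            pass
    return name, None, None


def read_alignments(
    path: str | os.PathLike,
    pass_tag: str = "np",
    barcode_tag: str = "BC",
    umi_tag: str = "RX",
) -> Iterator[AlignedRead]:
    """Stream primary alignments from a SAM/BAM file as :class:`AlignedRead`.

    Records matching the exclusion flag set (unmapped, secondary,
    supplementary, QC-fail, duplicate — samtools ``-F 3844``) are skipped, so
    supplementary alignments never reach tail extraction.  Barcode and pass
    count are parsed from colon-delimited read names (``ccs:barcode:pass``)
    when present, otherwise taken from the configured SAM tags; a read whose
    pass count cannot be determined is kept with ``pass_count=None`` and is
    excluded later by the pass filters.
    """
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as fh:
        for rec in fh:
            if rec.flag & EXCLUDE_FLAGS:
                continue
            try:
                yield _to_aligned_read(rec, pass_tag, barcode_tag, umi_tag)
            except AlignmentParseError:
                raise
            except Exception as exc:  # malformed CIGAR / fields
                raise AlignmentParseError(
                    f"cannot parse alignment record {rec.query_name!r}: {exc}"
                ) from exc


def _to_aligned_read(
    rec: "pysam.AlignedSegment", pass_tag: str, barcode_tag: str, umi_tag: str
) -> AlignedRead:
    name = rec.query_name or ""
    read_id, barcode, pass_count = _parse_read_name(name)
    if pass_count is None and rec.has_tag(pass_tag):
        pass_count = int(rec.get_tag(pass_tag))
    if barcode is None:
        barcode = str(rec.get_tag(barcode_tag)) if rec.has_tag(barcode_tag) else ""
    umi = str(rec.get_tag(umi_tag)) if rec.has_tag(umi_tag) else None

    cig = rec.cigartuples
    if cig is None:
        raise AlignmentParseError(f"record {name!r} has no CIGAR")
    seq = rec.query_sequence or ""
    quals = rec.query_qualities
    n5 = cig[0][1] if cig[0][0] == _SOFT_CLIP else 0
    n3 = cig[-1][1] if len(cig) > 1 and cig[-1][0] == _SOFT_CLIP else 0
    clip5 = seq[:n5]
    clip3 = seq[len(seq) - n3:] if n3 else ""
    q5 = list(quals[:n5]) if quals is not None and n5 else None
    q3 = list(quals[len(seq) - n3:]) if quals is not None and n3 else None

    return AlignedRead(
        read_id=read_id,
        barcode=barcode,
        pass_count=pass_count,
        chrom=rec.reference_name or "",
        strand="-" if rec.is_reverse else "+",
        aln_start=rec.reference_start + 1,
        aln_end=rec.reference_end,
        clip5=clip5,
        clip3=clip3,
        umi=umi,
        is_supplementary=rec.is_supplementary,
        clip5_qualities=q5,
        clip3_qualities=q3,
    )


def read_gene_models(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Parse a GTF file into :class:`GeneModel` objects keyed by gene id.

    Exons from all transcripts of a gene are merged; the last exon is
    computed in transcript orientation.  A gene feature without exons is
    rejected.
    """
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: dict[str, GeneModel] = {}
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    cds_by_gene: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, tuple[int, int]]] = {}

    for feat in db.all_features():
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            continue
        if feat.featuretype == "gene":
            meta[gid] = (feat.seqid, feat.strand, (feat.start, feat.end))
        elif feat.featuretype == "exon":
            exons_by_gene.setdefault(gid, []).append((feat.start, feat.end))
        elif feat.featuretype == "CDS":
            cds_by_gene.setdefault(gid, []).append((feat.start, feat.end))

    for gid, (chrom, strand, span) in meta.items():
        exons = _merge_intervals(exons_by_gene.get(gid, []))
        if not exons:
            raise ValueError(f"gene {gid} has no exon features")
        cds = _merge_intervals(cds_by_gene.get(gid, [])) or None
        models[gid] = GeneModel(
            gene_id=gid, chrom=chrom, strand=strand, exons=exons, cds=cds,
            gene_span=span,
        )
    # genes present only through exon lines still get a model
    for gid, exons in exons_by_gene.items():
        if gid in models:
            continue
        merged = _merge_intervals(exons)
        chrom = strand = None
        for feat in db.features_of_type("exon"):
            if feat.attributes.get("gene_id", [None])[0] == gid:
                chrom, strand = feat.seqid, feat.strand
                break
        models[gid] = GeneModel(
            gene_id=gid, chrom=chrom or "", strand=strand or "+",
            exons=merged, cds=_merge_intervals(cds_by_gene.get(gid, [])) or None,
        )
    return models


def _merge_intervals(ivals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_gene_assignment(path: str | os.PathLike) -> dict[str, str]:
    """Parse a featureCounts CORE-style table into a read→gene map.

    Columns: read id, assignment status, hit count, target gene id.  Only
    rows whose status is ``Assigned`` contribute; conflicting duplicate read
    ids raise.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=4 columns, got {len(cols)}"
                )
            read_id, status, _, gene_id = cols[0], cols[1], cols[2], cols[3]
            if status != "Assigned":
                continue
            if read_id in mapping and mapping[read_id] != gene_id:
                raise ValueError(
                    f"{path}: line {lineno}: read {read_id} assigned to both "
                    f"{mapping[read_id]} and {gene_id}"
                )
            mapping[read_id] = gene_id
    return mapping


# -- 13-column tail table (polyA_note layout) --------------------------------

_EMPTY_TAIL = "-"  # placeholder for 0-nt tails so every row has 13 fields

TAIL_TABLE_NCOLS = 13


def write_tail_records(records: Iterable[TailRecord], path: str | os.PathLike) -> None:
    """Write tail records as the fixed 13-column tab-separated table."""
    with open(path, "w") as fh:
        for rec in records:
            rec.validate()
            fh.write(
                "\t".join(
                    (
                        rec.barcode,
                        rec.read_id,
                        rec.gene_id,
                        str(rec.pass_count),
                        "1",
                        str(rec.count_a),
                        str(rec.count_t),
                        str(rec.count_c),
                        str(rec.count_g),
                        str(rec.count_nona),
                        "0",
                        rec.tail_seq or _EMPTY_TAIL,
                        repr(rec.mean_tail_qv),
                    )
                )
                + "\n"
            )


def read_tail_records(path: str | os.PathLike) -> list[TailRecord]:
    """Read a 13-column tail table; inverse of :func:`write_tail_records`."""
    out: list[TailRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != TAIL_TABLE_NCOLS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {TAIL_TABLE_NCOLS} columns, "
                    f"got {len(cols)}"
                )
            seq = "" if cols[11] == _EMPTY_TAIL else cols[11]
            out.append(
                TailRecord(
                    barcode=cols[0],
                    read_id=cols[1],
                    gene_id=cols[2],
                    pass_count=int(cols[3]),
                    count_a=int(cols[5]),
                    count_t=int(cols[6]),
                    count_c=int(cols[7]),
                    count_g=int(cols[8]),
                    count_nona=int(cols[9]),
                    tail_seq=seq,
                    mean_tail_qv=float(cols[12]),
                )
            )
    return out


# -- PAS catalog CSV ---------------------------------------------------------

PAS_CATALOG_COLUMNS = ["gene_id", "chrom", "strand", "position", "support", "label"]


def write_pas_catalog(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a PAS catalog table (gene_id, chrom, strand, position, support, label)."""
    missing = [c for c in PAS_CATALOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"PAS catalog frame missing columns: {missing}")
    frame.loc[:, PAS_CATALOG_COLUMNS].to_csv(path, index=False)


def read_pas_catalog(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"gene_id": str, "chrom": str, "strand": str,
                                     "label": str})
    missing = [c for c in PAS_CATALOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: PAS catalog missing columns: {missing}")
    frame["position"] = frame["position"].astype(int)
    frame["support"] = frame["support"].astype(int)
    return frame
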