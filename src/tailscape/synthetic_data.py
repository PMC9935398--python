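"""Synthetic genomes, annotations and tailed long reads with ground truth.

The generator emulates the maternal-mRNA remodeling regime seen across the
oocyte-to-embryo transition: per-gene read counts, lognormal-like tail
lengths, a configurable fraction of polyadenylated degradation intermediates
(reads whose 3′ end falls upstream of the polyadenylation site, occasionally
reaching into the CDS), internal consecutive-U runs whose distance from the
tail origin (N length) concentrates near zero, sparse mono C/G residues,
realistic pass-count spread, and optional UMI-tagged PCR duplication.

Reads are emitted pre-aligned as SAM records with the tail as a terminal
soft clip (reverse-complemented on the − strand), so the ground truth of
every read — gene, end position, PIT/PDI category, pre-error tail — is
exact.  The same seed yields byte-identical output files.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .io_formats import GeneModel
from .tail_extract import reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Generative parameters; defaults follow the one-cell-embryo regime.

    Tail lengths are lognormal with the given median (geometric mean) and
    log-sd.  ``p_pdi`` is the fraction of reads re-polyadenylated on a
    partially degraded 3′ end; degradation offsets are drawn uniformly
    upstream of the used PAS across the 3′-UTR plus a short CDS incursion
    (degradation shows no positional hotspots), with a geometric
    alternative available.  ``p_u`` is the probability a tail carries a
    consecutive-U run; the N length (tail 5′ origin to the run) is 0 with
    probability ``p_n0`` and otherwise short-geometric.
    """

    seed: int = 0
    n_genes: int = 50
    chrom: str = "synth1"
    chrom_length: Optional[int] = None  # None: sized to fit the genes

    # expression: reads per gene, gamma-Poisson (negative binomial)
    expr_mean: float = 100.0
    expr_dispersion: float = 0.1

    # gene / isoform structure
    p_two_pas: float = 0.3
    distal_usage: float = 0.7
    pas_spacing: int = 100
    exon1_length: int = 300
    intron_length: int = 100
    cds_in_last_exon: int = 120
    utr3_length: int = 180

    # tail length, lognormal
    tail_median: float = 33.0
    tail_log_sd: float = 0.45

    # degradation intermediates
    p_pdi: float = 0.6
    degradation_model: str = "uniform"  # or "geometric"
    # visible 3'-UTR shortening spans tens of nt; ends closer than ~3x the
    # 5-nt assignment window to a PAS are operationally indistinguishable
    # from intact ends, so degraded ends start at least this far upstream
    degradation_min_offset: int = 15
    degradation_geom_mean: float = 40.0
    cds_incursion: int = 20

    # non-A residues
    p_u: float = 0.6
    u_run_mean: float = 4.0
    p_end3_u: float = 0.0
    p_n0: float = 0.3
    n_length_mean: float = 6.0
    n_length_max: int = 15
    mono_c_rate: float = 0.004
    mono_g_rate: float = 0.003

    # sequencing
    error_rate: float = 0.001
    pass_mean: float = 18.0
    p_low_pass: float = 0.08
    aligned_len_min: int = 60
    aligned_len_max: int = 140
    base_quality: int = 40

    # library metadata
    barcode: str = "bc01"
    with_umi: bool = False
    umi_dup_rate: float = 0.0

    def validate(self) -> None:
        for name in (
            "p_two_pas", "distal_usage", "p_pdi", "p_u", "p_end3_u", "p_n0",
            "p_low_pass", "mono_c_rate", "mono_g_rate", "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.degradation_model not in ("uniform", "geometric"):
            raise ValueError(f"unknown degradation_model {self.degradation_model!r}")
        if self.tail_median < 1:
            raise ValueError("tail_median must be >= 1")


#: parameter bundles loosely emulating the studied stages; conveniences,
#: not claims of fidelity to any real sample.
_PRESETS = {
    "GV": dict(tail_median=37.0, p_pdi=0.15, p_u=0.15),
    "MII": dict(tail_median=63.0, p_pdi=0.15, p_u=0.30),
    "1C": dict(tail_median=33.0, p_pdi=0.60, p_u=0.60),
    "somatic": dict(tail_median=70.0, p_pdi=0.15, p_u=0.12, u_run_mean=1.3),
}


def stage_preset(name: str, **overrides) -> SimulationConfig:
    """A documented parameter bundle for a named stage (GV, MII, 1C, somatic)."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        )
    cfg = SimulationConfig(**_PRESETS[name])
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class _SynthGene:
    """Internal gene layout with a transcript-to-genome coordinate map."""

    gene_id: str
    strand: str
    g_start: int  # 1-based genomic start of the gene span
    exon1_length: int
    intron_length: int
    last_exon_length: int
    utr3_length: int

    @property
    def span_length(self) -> int:
        return self.exon1_length + self.intron_length + self.last_exon_length

    @property
    def g_end(self) -> int:
        return self.g_start + self.span_length - 1

    @property
    def tx_length(self) -> int:
        return self.exon1_length + self.last_exon_length

    def genomic_exons(self) -> list[tuple[int, int]]:
        g0 = self.g_start
        e1 = (g0, g0 + self.exon1_length - 1)
        e2 = (g0 + self.exon1_length + self.intron_length, self.g_end)
        return [e1, e2]

    def tx2g(self, t: int) -> int:
        """Map a 1-based transcript coordinate to a genomic coordinate."""
        if not 1 <= t <= self.tx_length:
            raise ValueError(f"transcript coordinate {t} outside 1..{self.tx_length}")
        if self.strand == "+":
            if t <= self.exon1_length:
                return self.g_start + t - 1
            return self.g_start + self.exon1_length + self.intron_length + (
                t - self.exon1_length - 1
            )
        # − strand: transcript runs genome-descending
        if t <= self.exon1_length:
            return self.g_end - (t - 1)
        return self.g_start + self.last_exon_length - 1 - (
            t - self.exon1_length - 1
        )

    def tx_interval_to_genomic(self, t_lo: int, t_hi: int) -> tuple[int, int]:
        """Genomic interval of a transcript interval contained in one exon."""
        a, b = self.tx2g(t_lo), self.tx2g(t_hi)
        return (a, b) if a <= b else (b, a)

    def exon_tx_bounds(self, t: int) -> tuple[int, int]:
        """Transcript bounds of the exon containing transcript coordinate ``t``."""
        if t <= self.exon1_length:
            return 1, self.exon1_length
        return self.exon1_length + 1, self.tx_length


@dataclass
class SimulatedDataset:
    """Paths and in-memory ground truth for one simulated sample."""

    genome_path: Path
    gtf_path: Path
    sam_path: Path
    truth_path: Path
    truth: pd.DataFrame
    genes: dict[str, GeneModel]
    pas_truth: dict[str, list[int]]  # genomic PAS positions per gene


def simulate_dataset(config: SimulationConfig, out_dir: str | os.PathLike) -> SimulatedDataset:
    """Generate genome FASTA, GTF, aligned SAM and ground-truth tables.

    Deterministic under a fixed config (including the seed): running twice
    produces byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = _place_genes(config, rng)
    chrom_len = config.chrom_length or (genes[-1].g_end + 200 if genes else 1000)
    if genes and genes[-1].g_end > chrom_len:
        raise ValueError(
            f"chrom_length {chrom_len} cannot fit {config.n_genes} genes "
            f"(need >= {genes[-1].g_end})"
        )
    genome = "".join(rng.choice(_BASES, size=chrom_len))

    pas_by_gene: dict[str, list[int]] = {}  # transcript coordinates
    for g, two in zip(genes, rng.random(len(genes)) < config.p_two_pas):
        distal = g.tx_length
        pas = [distal - config.pas_spacing, distal] if two else [distal]
        pas_by_gene[g.gene_id] = pas

    sam_rows: list[dict] = []
    truth_rows: list[dict] = []
    for gi, g in enumerate(genes):
        n_mol = _draw_read_count(config, rng)
        pas_tx = pas_by_gene[g.gene_id]
        for mi in range(n_mol):
            mol = _simulate_molecule(config, rng, g, pas_tx, gi, mi)
            n_copies = 1
            if config.with_umi and config.umi_dup_rate > 0:
                n_copies += int(rng.poisson(config.umi_dup_rate))
            for ci in range(n_copies):
                read = _emit_read(config, rng, g, mol, ci, genome)
                sam_rows.append(read)
                truth_rows.append(
                    {
                        "read_id": read["read_id"],
                        "gene_id": g.gene_id,
                        "barcode": config.barcode,
                        "umi": mol["umi"] or "",
                        "pass_count": read["pass_count"],
                        "strand": g.strand,
                        "end_genomic": mol["end_genomic"],
                        "category": mol["category"],
                        "pas_used": mol["pas_used_genomic"],
                        "tail_seq_true": mol["tail_true"],
                        "u_run_len": mol["u_run_len"],
                        "u_run_start": mol["u_run_start"],
                        "dup_group": mol["dup_group"],
                        "is_duplicate": ci > 0,
                    }
                )

    genome_path = out / "genome.fa"
    gtf_path = out / "genes.gtf"
    sam_path = out / "reads.sam"
    truth_path = out / "truth.tsv"

    _write_fasta(genome_path, config.chrom, genome)
    _write_gtf(gtf_path, config.chrom, genes)
    _write_sam(sam_path, config, genome, sam_rows, chrom_len)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(truth_path, sep="\t", index=False)

    models = {m.gene_id: m for m in (_to_gene_model(config.chrom, g) for g in genes)}
    pas_genomic = {
        g.gene_id: sorted(g.tx2g(t) for t in pas_by_gene[g.gene_id]) for g in genes
    }
    return SimulatedDataset(
        genome_path, gtf_path, sam_path, truth_path, truth, models, pas_genomic
    )


# -- internals ---------------------------------------------------------------


def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> list[_SynthGene]:
    spacing = 200
    genes = []
    cursor = 101
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)
    for i in range(config.n_genes):
        g = _SynthGene(
            gene_id=f"g{i + 1:04d}",
            strand=str(strands[i]),
            g_start=cursor,
            exon1_length=config.exon1_length,
            intron_length=config.intron_length,
            last_exon_length=config.cds_in_last_exon + config.utr3_length,
            utr3_length=config.utr3_length,
        )
        genes.append(g)
        cursor = g.g_end + spacing + 1
    return genes


def _draw_read_count(config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.expr_dispersion <= 0:
        return int(rng.poisson(config.expr_mean))
    shape = 1.0 / config.expr_dispersion
    lam = rng.gamma(shape, config.expr_mean / shape)
    return int(rng.poisson(lam))


_PIT_JITTER = np.array([-2, -1, 0, 1, 2])
_PIT_JITTER_P = np.array([0.05, 0.10, 0.70, 0.10, 0.05])


def _simulate_molecule(
    config: SimulationConfig,
    rng: np.random.Generator,
    g: _SynthGene,
    pas_tx: list[int],
    gene_index: int,
    mol_index: int,
) -> dict:
    cds_end_tx = config.exon1_length + config.cds_in_last_exon
    pas = pas_tx[-1]
    if len(pas_tx) == 2 and rng.random() >= config.distal_usage:
        pas = pas_tx[0]

    if rng.random() < config.p_pdi:
        end_tx = _draw_degraded_end(config, rng, g, pas, pas_tx, cds_end_tx)
    else:
        jitter = int(rng.choice(_PIT_JITTER, p=_PIT_JITTER_P))
        end_tx = min(g.tx_length, max(1, pas + jitter))

    # category follows the realized geometry, not the sampling branch
    if any(abs(end_tx - p) <= 5 for p in pas_tx):
        category = "PIT"
    elif any(end_tx < p - 5 for p in pas_tx):
        category = "PDI"
    else:  # pragma: no cover - geometry excludes this
        category = "UNASSIGNED"

    tail, run_len, run_start = _simulate_tail(config, rng)
    umi = _umi_code(gene_index, mol_index) if config.with_umi else None
    return {
        "end_tx": end_tx,
        "end_genomic": g.tx2g(end_tx),
        "pas_used_genomic": g.tx2g(pas),
        "category": category,
        "tail_true": tail,
        "u_run_len": run_len,
        "u_run_start": run_start,
        "umi": umi,
        "dup_group": f"{g.gene_id}.m{mol_index:05d}",
        "mol_index": mol_index,
    }


def _draw_degraded_end(
    config: SimulationConfig,
    rng: np.random.Generator,
    g: _SynthGene,
    pas: int,
    pas_tx: list[int],
    cds_end_tx: int,
) -> int:
    lo = config.degradation_min_offset
    hi = max(lo, pas - (cds_end_tx - config.cds_incursion))
    for _ in range(1000):
        if config.degradation_model == "uniform":
            offset = int(rng.integers(lo, hi + 1))
        else:
            offset = lo + int(rng.geometric(1.0 / config.degradation_geom_mean)) - 1
            offset = min(offset, hi)
        end_tx = max(1, pas - offset)
        # keep degraded ends clear of every PAS window so truth equals intent
        if all(abs(end_tx - p) > 5 for p in pas_tx):
            return end_tx
    raise RuntimeError("could not place a degraded 3' end clear of PAS windows")


def _simulate_tail(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, int, int]:
    length = max(
        1, int(round(rng.lognormal(math.log(config.tail_median), config.tail_log_sd)))
    )
    run_len = 0
    run_start = -1
    if rng.random() < config.p_u:
        run_len = min(30, int(rng.geometric(1.0 / config.u_run_mean)))
        if config.p_end3_u > 0 and rng.random() < config.p_end3_u:
            length = max(length, run_len + 1)
            run_start = length - run_len
        else:
            if rng.random() < config.p_n0:
                run_start = 0
            else:
                run_start = min(
                    config.n_length_max,
                    int(rng.geometric(1.0 / config.n_length_mean)),
                )
            length = max(length, run_start + run_len + 1)
    tail = np.full(length, "A")
    if run_len:
        tail[run_start : run_start + run_len] = "T"
    # sparse mono C/G on remaining A positions
    a_mask = tail == "A"
    draws = rng.random(length)
    tail[a_mask & (draws < config.mono_c_rate)] = "C"
    tail[
        a_mask
        & (draws >= config.mono_c_rate)
        & (draws < config.mono_c_rate + config.mono_g_rate)
    ] = "G"
    return "".join(tail), run_len, run_start


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if hit.any():
        subs = rng.integers(1, 4, size=int(hit.sum()))
        base_idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(base_idx + subs) % 4]
    return "".join(arr)


def _umi_code(gene_index: int, mol_index: int) -> str:
    """Deterministic unique 10-mer (base-4 code of gene and molecule index)."""
    value = gene_index * 100_000 + mol_index
    letters = []
    for _ in range(10):
        letters.append("ACGT"[value % 4])
        value //= 4
    return "".join(letters)


def _emit_read(
    config: SimulationConfig,
    rng: np.random.Generator,
    g: _SynthGene,
    mol: dict,
    copy_index: int,
    genome: str,
) -> dict:
    end_tx = mol["end_tx"]
    t_lo, _ = g.exon_tx_bounds(end_tx)
    aln_len = int(rng.integers(config.aligned_len_min, config.aligned_len_max + 1))
    start_tx = max(t_lo, end_tx - aln_len + 1)
    g_lo, g_hi = g.tx_interval_to_genomic(start_tx, end_tx)

    tail = _apply_errors(mol["tail_true"], config.error_rate, rng)

    if rng.random() < config.p_low_pass:
        pass_count = int(rng.integers(1, 10))
    else:
        pass_count = 1 + int(rng.poisson(config.pass_mean))

    rid = f"{mol['dup_group']}" + (f".d{copy_index}" if copy_index else "")
    ref_seq = genome[g_lo - 1 : g_hi]
    if g.strand == "+":
        seq = ref_seq + tail
        cigar = f"{len(ref_seq)}M{len(tail)}S" if tail else f"{len(ref_seq)}M"
        flag = 0
    else:
        seq = reverse_complement(tail) + ref_seq
        cigar = f"{len(tail)}S{len(ref_seq)}M" if tail else f"{len(ref_seq)}M"
        flag = 16
    return {
        "read_id": rid,
        "qname": f"{rid}:{config.barcode}:{pass_count}",
        "flag": flag,
        "pos": g_lo,
        "cigar": cigar,
        "seq": seq,
        "pass_count": pass_count,
        "umi": mol["umi"],
    }


def _write_fasta(path: Path, chrom: str, genome: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), 80):
            fh.write(genome[i : i + 80] + "\n")


def _write_gtf(path: Path, chrom: str, genes: list[_SynthGene]) -> None:
    def line(feature: str, start: int, end: int, strand: str, attrs: str) -> str:
        return (
            f"{chrom}\ttailscape_sim\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
        )

    with open(path, "w") as fh:
        for g in genes:
            attrs_gene = f'gene_id "{g.gene_id}";'
            attrs_tx = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(line("gene", g.g_start, g.g_end, g.strand, attrs_gene))
            fh.write(line("transcript", g.g_start, g.g_end, g.strand, attrs_tx))
            for s, e in g.genomic_exons():
                fh.write(line("exon", s, e, g.strand, attrs_tx))
            # CDS spans exon1 fully plus the first part of the last exon
            c1 = g.tx_interval_to_genomic(1, g.exon1_length)
            c2 = g.tx_interval_to_genomic(
                g.exon1_length + 1,
                g.exon1_length + (g.last_exon_length - g.utr3_length),
            )
            for s, e in sorted([c1, c2]):
                fh.write(line("CDS", s, e, g.strand, attrs_tx))


def _write_sam(
    path: Path,
    config: SimulationConfig,
    genome: str,
    rows: list[dict],
    chrom_len: int,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom, "LN": chrom_len}],
    }
    rows = sorted(rows, key=lambda r: (r["pos"], r["qname"]))
    qual_char = config.base_quality
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as fh:
        for r in rows:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = r["qname"]
            seg.flag = r["flag"]
            seg.reference_id = 0
            seg.reference_start = r["pos"] - 1
            seg.mapping_quality = 60
            seg.cigarstring = r["cigar"]
            seg.query_sequence = r["seq"]
            seg.query_qualities = pysam.qualitystring_to_array(
                chr(qual_char + 33) * len(r["seq"])
            )
            tags = [("np", r["pass_count"])]
            if r["umi"]:
                tags.append(("RX", r["umi"]))
            seg.set_tags(tags)
            fh.write(seg)


def _to_gene_model(chrom: str, g: _SynthGene) -> GeneModel:
    cds_tx_hi = g.exon1_length + (g.last_exon_length - g.utr3_length)
    c1 = g.tx_interval_to_genomic(1, g.exon1_length)
    c2 = g.tx_interval_to_genomic(g.exon1_length + 1, cds_tx_hi)
    return GeneModel(
        gene_id=g.gene_id,
        chrom=chrom,
        strand=g.strand,
        exons=g.genomic_exons(),
        cds=sorted([c1, c2]),
        gene_span=(g.g_start, g.g_end),
    )
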