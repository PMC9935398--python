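"""Transcript- and gene-level summaries of tails, PDIs and expression.

Gene tail length is the geometric mean over its poly(A)+ reads, because
per-gene tail-length distributions are lognormal-like.  Non-A and PDI
proportions are per-transcript fractions, aggregated per gene only when the
gene has at least 20 qualifying reads.  Expression is quantified as CPM and
compared between groups with a Student's t-test on CPM values, flagging
genes at |log2 fold change| >= 0.5 and P < 0.05.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TailRecord
from .pas_pdi import PDI, PIT, PasSite, ReadEndAssignment
from .tail_stats import residue_position_class

MIN_GENE_READS = 20


def geometric_mean_tail_length(lengths: Iterable[float]) -> float:
    """exp(mean(log length)); NaN for empty input.  Lengths must be >= 1."""
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size == 0:
        return float("nan")
    if (arr < 1).any():
        raise ValueError("geometric mean is defined for tails of length >= 1")
    return float(stats.gmean(arr))


def transcript_nona_proportion(
    records: Sequence[TailRecord],
    base: str,
    position: Optional[str] = None,
    collapse_end3_to_internal: bool = False,
) -> float:
    """Fraction of tails containing the given non-A base.

    ``position`` restricts to tails whose residue falls in the ``end3`` or
    ``internal`` class; ``None`` counts any occurrence.
    """
    if not records:
        return float("nan")
    n = 0
    for rec in records:
        cls = residue_position_class(rec.tail_seq, base, collapse_end3_to_internal)
        if cls == "none":
            continue
        if position is None or cls == position:
            n += 1
    return n / len(records)


def gene_nona_proportion(
    records: Sequence[TailRecord],
    base: str,
    position: Optional[str] = None,
    collapse_end3_to_internal: bool = False,
    min_reads: int = MIN_GENE_READS,
) -> pd.Series:
    """Per-gene non-A fraction over genes with >= ``min_reads`` poly(A)+ reads."""
    by_gene: dict[str, list[TailRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    out = {
        gid: transcript_nona_proportion(recs, base, position, collapse_end3_to_internal)
        for gid, recs in by_gene.items()
        if len(recs) >= min_reads
    }
    return pd.Series(out, dtype=float).sort_index()


def pdi_proportion(assignments: Iterable[ReadEndAssignment]) -> Optional[float]:
    """#PDI / (#PDI + #PIT); unassigned reads are excluded from the denominator."""
    n_pdi = n_pit = 0
    for a in assignments:
        if a.category == PDI:
            n_pdi += 1
        elif a.category == PIT:
            n_pit += 1
    if n_pdi + n_pit == 0:
        return None
    return n_pdi / (n_pdi + n_pit)


def gene_pdi_proportion(
    assignments: Iterable[ReadEndAssignment], min_reads: int = MIN_GENE_READS
) -> pd.Series:
    """Per-gene PDI proportion over genes with #PDI + #PIT >= ``min_reads``."""
    by_gene: dict[str, list[ReadEndAssignment]] = {}
    for a in assignments:
        by_gene.setdefault(a.gene_id, []).append(a)
    out = {}
    for gid, gene_assign in by_gene.items():
        informative = [a for a in gene_assign if a.category in (PDI, PIT)]
        if len(informative) >= min_reads:
            out[gid] = pdi_proportion(informative)
    return pd.Series(out, dtype=float).sort_index()


def avg_u_length_per_tail(
    records: Sequence[TailRecord],
    assignments: Optional[Iterable[ReadEndAssignment]] = None,
    restrict: Optional[str] = None,
) -> float:
    """Sum of U residues over all tails divided by the number of tails.

    With ``restrict='PDI'`` (or ``'PIT'``) both the numerator and the
    denominator use only reads of that category, per ``assignments``.
    """
    if restrict is not None:
        if assignments is None:
            raise ValueError("restrict requires assignments")
        keep = {a.read_id for a in assignments if a.category == restrict}
        records = [r for r in records if r.read_id in keep]
    if not records:
        return float("nan")
    return sum(r.count_t for r in records) / len(records)


def apa_isoform_tail_comparison(
    sites: Sequence[PasSite],
    assignments: Iterable[ReadEndAssignment],
    records: Sequence[TailRecord],
    min_reads: int = MIN_GENE_READS,
) -> Optional[tuple[float, float]]:
    """Geometric-mean tail length of the pPAS and dPAS isoforms of one gene.

    PIT reads are grouped by their matched site; the gene qualifies only
    when both isoforms have at least ``min_reads`` poly(A)+ reads.  Returns
    (pPAS mean, dPAS mean) or ``None`` if not comparable.
    """
    labels = {s.position: s.label for s in sites}
    if sorted(labels.values()) != ["dPAS", "pPAS"]:
        return None
    tail_len = {r.read_id: len(r.tail_seq) for r in records}
    grouped: dict[str, list[int]] = {"pPAS": [], "dPAS": []}
    for a in assignments:
        if a.category != PIT or a.matched_pas not in labels:
            continue
        length = tail_len.get(a.read_id)
        if length is not None and length >= 1:
            grouped[labels[a.matched_pas]].append(length)
    if len(grouped["pPAS"]) < min_reads or len(grouped["dPAS"]) < min_reads:
        return None
    return (
        geometric_mean_tail_length(grouped["pPAS"]),
        geometric_mean_tail_length(grouped["dPAS"]),
    )


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: 1e6 * count / column total (genes x samples).

    Counts should include every read with at least one pass assigned to a
    gene; each output column sums to 1e6.
    """
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero total reads in sample(s): {bad}")
    return counts * 1_000_000.0 / totals


def differential_expression(
    cpm_a: pd.DataFrame,
    cpm_b: pd.DataFrame,
    pseudocount: float = 1.0,
    alternative: str = "two-sided",
    equal_var: bool = True,
    lfc_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene log2 fold change and t-test between two replicate groups.

    ``log2fc = log2((mean_B + eps) / (mean_A + eps))`` with a pseudocount
    (default 1 CPM) guarding against zero means.  P values come from a
    Student's (equal-variance) two-sample t-test on CPM values; a one-tailed
    test with a fixed direction is available through ``alternative``
    ('greater' tests B > A).  Genes with zero variance in both groups and
    equal means get P = 1.  Flags: 'up' / 'down' at |log2fc| >=
    ``lfc_threshold`` and P < ``p_threshold``, else ''.
    """
    genes = cpm_a.index
    if not genes.equals(cpm_b.index):
        raise ValueError("group A and B must share the same gene index")
    a = cpm_a.to_numpy(dtype=float)
    b = cpm_b.to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("at least two replicates per group are required")
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate zero-variance genes are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(
            b, a, axis=1, equal_var=equal_var, alternative=alternative
        )
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    p[degenerate & (mean_a == mean_b)] = 1.0
    p[degenerate & (mean_a != mean_b)] = 0.0
    flag = np.where(
        (np.abs(log2fc) >= lfc_threshold) & (p < p_threshold),
        np.where(log2fc > 0, "up", "down"),
        "",
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "flag": flag}, index=genes
    )


def tail_length_histogram(
    lengths: Iterable[int], max_len: int = 250
) -> tuple[np.ndarray, float]:
    """1-nt-binned tail-length density (overflow pooled at ``max_len``) and median.

    The density indexes length 0..max_len and sums to 1; the median is
    computed on the unbinned lengths.
    """
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size == 0:
        return np.zeros(max_len + 1), float("nan")
    median = float(np.median(arr))
    clipped = np.clip(arr.astype(int), 0, max_len)
    density = np.bincount(clipped, minlength=max_len + 1) / arr.size
    return density, median


def filter_gene_universe(
    records: Sequence[TailRecord], exclude: Iterable[str]
) -> list[TailRecord]:
    """Drop records of excluded genes (e.g. histone or rRNA gene lists)."""
    excluded = set(exclude)
    return [r for r in records if r.gene_id not in excluded]
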