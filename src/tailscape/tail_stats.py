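"""Per-read residue statistics on poly(A) tails.

A tail is scanned for non-A residues (U is written T in cDNA; user-facing
labels print U).  For each base the longest consecutive run is measured and
bucketed (U: single / 2-5 / >=6; C and G: single / 2 / >=3), the residue is
assigned a 3′-end or internal position class, and for uridylated tails the
"N length" — the number of residues between the tail's 5′ origin (the end of
the 3′-UTR) and the first base of the unique longest U run — is computed.
A tail whose longest U run is tied between several stretches has no defined
N length and is discarded from that analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import TailRecord

NON_A_BASES = ("T", "C", "G")

#: run-length partition per base; upper bound inclusive, None = open
_RUN_GROUPS = {
    "T": (("U1", 1, 1), ("U2-5", 2, 5), ("U>=6", 6, None)),
    "C": (("C1", 1, 1), ("C2", 2, 2), ("C>=3", 3, None)),
    "G": (("G1", 1, 1), ("G2", 2, 2), ("G>=3", 3, None)),
}


def annotate_tail(
    read_id: str,
    gene_id: str,
    barcode: str,
    pass_count: int,
    tail_seq: str,
    qualities: Optional[Sequence[int]] = None,
) -> TailRecord:
    """Build the 13-column tail record for a TRUE-classified tail."""
    seq = tail_seq.upper()
    count_t, count_c, count_g = (seq.count(b) for b in NON_A_BASES)
    mean_qv = float(np.mean(qualities)) if qualities else 0.0
    return TailRecord(
        barcode=barcode,
        read_id=read_id,
        gene_id=gene_id,
        pass_count=pass_count,
        count_a=seq.count("A"),
        count_t=count_t,
        count_c=count_c,
        count_g=count_g,
        count_nona=count_t + count_c + count_g,
        tail_seq=seq,
        mean_tail_qv=mean_qv,
    )


def longest_run(tail: str, base: str) -> int:
    """Length of the longest consecutive run of ``base``; 0 if absent."""
    _check_base(base)
    best = 0
    for m in re.finditer(f"{base}+", tail.upper()):
        best = max(best, m.end() - m.start())
    return best


def run_group(tail: str, base: str) -> Optional[str]:
    """Bucket a tail by its longest consecutive run of ``base``.

    U runs partition into U1 / U2-5 / U>=6; C and G runs into 1 / 2 / >=3.
    ``None`` when the base does not occur.
    """
    _check_base(base)
    n = longest_run(tail, base)
    if n == 0:
        return None
    for label, lo, hi in _RUN_GROUPS[base]:
        if n >= lo and (hi is None or n <= hi):
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def residue_position_class(
    tail: str, base: str, collapse_end3_to_internal: bool = False
) -> str:
    """Assign a base to ``end3``, ``internal`` or ``none`` for a tail.

    The tail is scanned for 3′-end residues first: if the tail's terminal
    base is ``base`` (a terminal run of length >= 1) the tail is in the
    ``end3`` class regardless of additional internal occurrences.  With
    ``collapse_end3_to_internal`` every occurrence counts as internal,
    reproducing libraries that cannot capture 3′-terminal non-A residues and
    report all of them as internal.
    """
    _check_base(base)
    seq = tail.upper()
    if base not in seq:
        return "none"
    if not collapse_end3_to_internal and seq.endswith(base):
        return "end3"
    return "internal"


def n_length(tail: str) -> Optional[int]:
    """Offset of the unique longest U(T) run from the tail's 5′ end.

    This is the number of residues (of any kind) between the end of the
    3′-UTR and the first base of the longest consecutive U stretch.  When
    two or more runs tie for longest the N length is undefined (``None``)
    and the tail is discarded from N-length analyses.  Calling this on a
    tail with no T is an error.
    """
    runs = [(m.start(), m.end() - m.start()) for m in re.finditer("T+", tail.upper())]
    if not runs:
        raise ValueError("n_length is only defined for tails containing T/U")
    best = max(length for _, length in runs)
    starts = [start for start, length in runs if length == best]
    if len(starts) > 1:
        return None
    return starts[0]


@dataclass
class TailResidueProfile:
    """Per-tail residue summary across the three non-A bases."""

    tail_length: int
    longest_run: dict[str, int]
    run_group: dict[str, Optional[str]]
    position_class: dict[str, str]
    n_length: Optional[int]  # None: tied runs; also None when no U present


def tail_residue_profile(
    tail: str, collapse_end3_to_internal: bool = False
) -> TailResidueProfile:
    seq = tail.upper()
    runs = {b: longest_run(seq, b) for b in NON_A_BASES}
    groups = {b: run_group(seq, b) for b in NON_A_BASES}
    classes = {
        b: residue_position_class(seq, b, collapse_end3_to_internal)
        for b in NON_A_BASES
    }
    nlen = n_length(seq) if "T" in seq else None
    return TailResidueProfile(len(seq), runs, groups, classes, nlen)


def profile_table(
    records: Iterable[TailRecord], collapse_end3_to_internal: bool = False
) -> pd.DataFrame:
    """Per-read residue profile table (one row per tail record)."""
    rows = []
    for rec in records:
        prof = tail_residue_profile(rec.tail_seq, collapse_end3_to_internal)
        rows.append(
            {
                "read_id": rec.read_id,
                "gene_id": rec.gene_id,
                "tail_length": prof.tail_length,
                "longest_U_run": prof.longest_run["T"],
                "longest_C_run": prof.longest_run["C"],
                "longest_G_run": prof.longest_run["G"],
                "U_group": prof.run_group["T"],
                "C_group": prof.run_group["C"],
                "G_group": prof.run_group["G"],
                "U_position": prof.position_class["T"],
                "C_position": prof.position_class["C"],
                "G_position": prof.position_class["G"],
                "n_length": prof.n_length,
            }
        )
    cols = [
        "read_id", "gene_id", "tail_length",
        "longest_U_run", "longest_C_run", "longest_G_run",
        "U_group", "C_group", "G_group",
        "U_position", "C_position", "G_position", "n_length",
    ]
    return pd.DataFrame(rows, columns=cols)


def _check_base(base: str) -> None:
    if base not in NON_A_BASES:
        raise ValueError(f"base must be one of {NON_A_BASES}, got {base!r}")
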