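"""Block trimming of ambiguous alignment regions (Gblocks-style).

Columns are first classified, then blocks are carved out with three
rules: long stretches of unreliable columns are removed, surviving run
ends are trimmed back to well-conserved columns, and short leftover
blocks are dropped.  This is a declared simplification: the flank
refinement sub-steps of the original tool are omitted.
"""

from __future__ import annotations

import enum
from collections import Counter
from typing import Optional, Sequence

from .io import GAP, Msa


class ColumnClass(enum.Enum):
    GAP_POSITION = "gap_position"
    NONCONSERVED = "nonconserved"
    CONSERVED = "conserved"
    HIGHLY_CONSERVED = "highly_conserved"

    def __str__(self) -> str:
        return self.value


def classify_columns(
    msa: Msa,
    b1: Optional[int] = None,
    b2: float = 0.85,
    gap_rule: str = "half",
) -> list[ColumnClass]:
    """Label every column.

    gap_position iff the gap fraction is >= 0.5 ("half" rule); otherwise
    highly_conserved iff the modal residue reaches fraction ``b2`` of all
    rows, conserved iff the modal count reaches ``b1`` (default: strict
    majority, n//2 + 1), else nonconserved.
    """
    if gap_rule != "half":
        raise ValueError(f"unknown gap rule {gap_rule!r}")
    n = msa.n_rows
    conserved_min = b1 if b1 is not None else n // 2 + 1
    labels = []
    for c in range(msa.n_cols):
        col = msa.column(c)
        n_gap = col.count(GAP)
        if n_gap / n >= 0.5:
            labels.append(ColumnClass.GAP_POSITION)
            continue
        residues = Counter(ch for ch in col if ch != GAP)
        modal = residues.most_common(1)[0][1]
        if modal / n >= b2:
            labels.append(ColumnClass.HIGHLY_CONSERVED)
        elif modal >= conserved_min:
            labels.append(ColumnClass.CONSERVED)
        else:
            labels.append(ColumnClass.NONCONSERVED)
    return labels


_BAD = {ColumnClass.NONCONSERVED, ColumnClass.GAP_POSITION}


def kept_columns(
    labels: Sequence[ColumnClass],
    max_noncons: int = 15,
    min_block: int = 2,
) -> list[int]:
    """Indices of columns surviving the trimming rules, in order.

    1. contiguous runs of more than ``max_noncons`` unreliable
       (nonconserved or gap) columns are removed;
    2. each remaining run is trimmed at both ends back to the nearest
       conserved-or-better column;
    3. surviving blocks shorter than ``min_block`` are dropped.
    """
    n = len(labels)
    removed = [False] * n
    i = 0
    while i < n:
        if labels[i] in _BAD:
            j = i
            while j < n and labels[j] in _BAD:
                j += 1
            if j - i > max_noncons:
                for c in range(i, j):
                    removed[c] = True
            i = j
        else:
            i += 1

    kept: list[int] = []
    i = 0
    while i < n:
        if removed[i]:
            i += 1
            continue
        j = i
        while j < n and not removed[j]:
            j += 1
        block = list(range(i, j))
        while block and labels[block[0]] in _BAD:
            block.pop(0)
        while block and labels[block[-1]] in _BAD:
            block.pop()
        if len(block) >= min_block:
            kept.extend(block)
        i = j
    return kept


def trim_blocks(msa: Msa, max_noncons: int = 15, min_block: int = 2, **classify_kw) -> tuple[Msa, list[int]]:
    """Trimmed alignment plus the kept-column -> original-column map."""
    labels = classify_columns(msa, **classify_kw)
    cols = kept_columns(labels, max_noncons=max_noncons, min_block=min_block)
    return msa.take_columns(cols), cols


def write_column_map(path, cols: Sequence[int]) -> None:
    with open(path, "w") as fh:
        fh.write("kept\toriginal\n")
        for i, c in enumerate(cols):
            fh.write(f"{i}\t{c}\n")
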