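"""Excision of the N-terminal CBM4-like domain region from an alignment.

The domain is delimited by the conserved ``L-x-V-D`` (start) and
``S-x-x-P`` (end) anchor motifs located in alignment columns.  Both
anchors are included in the excised region: columns from the first
column of the start anchor through the last column of the end anchor.
Columns left of the start anchor are removed by default (the domain lies
*between* the motifs); ``keep_left=True`` preserves them and removes only
the columns after the end anchor, the literal protocol variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import DataError
from .io import Msa
from .motifs import MotifPattern, locate_conserved_motif


@dataclass(frozen=True)
class DomainSegment:
    """Ungapped residue interval of the excised domain in one sequence.

    ``start``/``end`` are 0-based half-open indices into the ungapped
    sequence of ``seq_id``.
    """

    seq_id: str
    start: int
    end: int
    anchor_columns: tuple[int, int]  # [first start-anchor col, last end-anchor col + 1)


def excise_domain_alignment(
    msa: Msa,
    start_pattern: MotifPattern,
    end_pattern: MotifPattern,
    min_fraction: float = 0.5,
    keep_left: bool = False,
) -> tuple[Msa, list[DomainSegment], list[str]]:
    """Cut the domain window out of an alignment.

    Returns ``(excised alignment, per-row segments, all-gap row ids)``.
    Rows that are entirely gaps inside the window are flagged and get no
    segment; callers exclude them from profile training.

    Raises :class:`DataError` when an anchor cannot be located or the
    anchors are out of order.
    """
    start_iv = locate_conserved_motif(msa, start_pattern, min_fraction)
    if start_iv is None:
        raise DataError(f"start anchor {start_pattern.name!r} not found in alignment")
    end_iv = locate_conserved_motif(msa, end_pattern, min_fraction)
    if end_iv is None:
        raise DataError(f"end anchor {end_pattern.name!r} not found in alignment")
    if start_iv[0] >= end_iv[0]:
        raise DataError(
            f"anchors out of order: {start_pattern.name} at column {start_iv[0]} "
            f"is not left of {end_pattern.name} at column {end_iv[0]}"
        )

    window = (0 if keep_left else start_iv[0], end_iv[1])
    cols = list(range(window[0], window[1]))
    excised = msa.take_columns(cols)

    segments: list[DomainSegment] = []
    all_gap: list[str] = []
    for rid, s in msa.rows:
        residue_positions = [
            msa.residue_index_of(rid, c) for c in cols if s[c] != "-"
        ]
        if not residue_positions:
            all_gap.append(rid)
            continue
        segments.append(
            DomainSegment(
                seq_id=rid,
                start=residue_positions[0],
                end=residue_positions[-1] + 1,
                anchor_columns=window,
            )
        )
    return excised, segments, all_gap


def write_segments(path, segments: list[DomainSegment]) -> None:
    """BED-like TSV: id, start, end (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("id\tstart\tend\n")
        for seg in segments:
            fh.write(f"{seg.seq_id}\t{seg.start}\t{seg.end}\n")
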