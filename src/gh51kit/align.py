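"""Global pairwise alignment and percent identity.

Needleman-Wunsch with affine gaps over a named substitution matrix
(default BLOSUM62, gap open 10, gap extend 0.5; a gap of length k costs
``open + (k - 1) * extend``).  The dynamic programming engine is
Biopython's :class:`PairwiseAligner`; this module owns the identity
conventions and report formats.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import DataError
from .io import GAP, ProteinRecord


@dataclass(frozen=True)
class PairwiseAlignment:
    """One global alignment: two gapped rows of equal length."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str
    score: float
    matrix: str
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise DataError("alignment rows must have equal length")
        for ca, cb in zip(self.row_a, self.row_b):
            if ca == GAP and cb == GAP:
                raise DataError("column gapped in both rows")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    try:
        sub = substitution_matrices.load(matrix)
    except FileNotFoundError:
        raise DataError(f"unknown substitution matrix {matrix!r}") from None
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of two protein records.

    Ties between co-optimal alignments are broken by the engine's
    canonical traceback order, which is deterministic.
    """
    if not a.sequence or not b.sequence:
        raise DataError("cannot align empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a.sequence, b.sequence)[0]
    return PairwiseAlignment(
        id_a=a.id,
        id_b=b.id,
        row_a=str(aln[0]),
        row_b=str(aln[1]),
        score=float(aln.score),
        matrix=matrix,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def percent_identity(aln: PairwiseAlignment, mode: str = "aligned_columns") -> float:
    """Percent identity of an alignment, one decimal, half-up.

    ``aligned_columns``: identities over columns where both rows hold
    residues.  ``shorter_seq``: identities over the length of the shorter
    input sequence.
    """
    identities = 0
    both = 0
    for ca, cb in zip(aln.row_a, aln.row_b):
        if ca != GAP and cb != GAP:
            both += 1
            if ca == cb:
                identities += 1
    if mode == "aligned_columns":
        denom = both
    elif mode == "shorter_seq":
        denom = min(
            len(aln.row_a) - aln.row_a.count(GAP),
            len(aln.row_b) - aln.row_b.count(GAP),
        )
    else:
        raise DataError(f"unknown identity mode {mode!r}")
    if denom == 0:
        raise DataError("zero denominator for percent identity")
    value = Decimal(100) * Decimal(identities) / Decimal(denom)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def write_pairwise_fasta(path, aln: PairwiseAlignment) -> None:
    with open(path, "w") as fh:
        fh.write(f">{aln.id_a}\n{aln.row_a}\n>{aln.id_b}\n{aln.row_b}\n")


def write_identity_report(path, rows: list[tuple[str, str, float, float]]) -> None:
    """TSV: id_a, id_b, score, percent identity."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tscore\tpercent_identity\n")
        for id_a, id_b, score, pid in rows:
            fh.write(f"{id_a}\t{id_b}\t{score:.1f}\t{pid}\n")
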