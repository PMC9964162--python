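"""Degenerate motif compilation and scanning, family validation, and
catalytic acid/base classification.

Motif strings are dash-separated tokens: a single residue (``G``), an
alternation (``E/Q``), or the wildcard ``x``.  The wildcard matches any
residue including ``X``; fixed and alternation tokens match canonical
residues only — an ``X`` in the sequence never satisfies them.

The family-membership filter keeps sequences of at least 350 residues
that carry both the acid/base motif ``G-N-E/Q`` and the nucleophile
motif ``S-E-Y-x-V`` simultaneously.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import DataError
from .io import AA20, Msa, ProteinRecord

logger = logging.getLogger(__name__)

WILDCARD = "x"

# Motif vocabulary used throughout the pipeline.
ACID_BASE_MOTIF = "G-N-E/Q"
NUCLEOPHILE_MOTIF = "S-E-Y-x-V"
DOMAIN_START_MOTIF = "L-x-V-D"
DOMAIN_END_MOTIF = "S-x-x-P"
DOMAIN_CORE_MOTIF = "G-x-x-F-E-x-I-x-x-x-G-x-G-G"

MIN_VALIDATION_LENGTH = 350


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate motif.

    ``tokens`` holds, per position, either ``None`` (wildcard) or a
    frozenset of allowed residues.
    """

    name: str
    tokens: tuple[Optional[frozenset[str]], ...]

    def __len__(self) -> int:
        return len(self.tokens)

    def __str__(self) -> str:
        return self.name

    def matches_at(self, seq: str, start: int) -> bool:
        if start < 0 or start + len(self.tokens) > len(seq):
            return False
        for tok, ch in zip(self.tokens, seq[start : start + len(self.tokens)]):
            if tok is None:
                continue
            if ch not in tok:
                return False
        return True


@dataclass(frozen=True)
class MotifHit:
    """One located motif occurrence (0-based ``start``)."""

    pattern_name: str
    seq_id: str
    start: int
    matched: str
    resolutions: tuple[str, ...]  # residue chosen at each wildcard/alternation position


def compile_pattern(text: str) -> MotifPattern:
    """Compile a dash-separated motif string into a :class:`MotifPattern`.

    >>> compile_pattern("G-N-E/Q").tokens[2] == frozenset("EQ")
    True
    """
    raw_tokens = text.split("-")
    if len(raw_tokens) < 2:
        raise DataError(f"motif {text!r}: must have at least 2 tokens")
    tokens: list[Optional[frozenset[str]]] = []
    for tok in raw_tokens:
        if tok == "":
            raise DataError(f"motif {text!r}: empty token")
        if tok == WILDCARD:
            tokens.append(None)
            continue
        residues = tok.split("/")
        for r in residues:
            if len(r) != 1 or r not in AA20:
                raise DataError(f"motif {text!r}: illegal token {tok!r}")
        tokens.append(frozenset(residues))
    return MotifPattern(name=text, tokens=tuple(tokens))


def scan_sequence(pattern: MotifPattern, record: ProteinRecord) -> list[MotifHit]:
    """All occurrences of ``pattern`` in the record, leftmost first.

    Overlapping occurrences are all reported.
    """
    return scan_string(pattern, record.sequence, record.id)


def scan_string(pattern: MotifPattern, seq: str, seq_id: str = "") -> list[MotifHit]:
    hits = []
    L = len(pattern)
    for start in range(len(seq) - L + 1):
        if pattern.matches_at(seq, start):
            window = seq[start : start + L]
            resolutions = tuple(
                ch
                for tok, ch in zip(pattern.tokens, window)
                if tok is None or len(tok) > 1
            )
            hits.append(MotifHit(pattern.name, seq_id, start, window, resolutions))
    return hits


class FailureReason(enum.Enum):
    TOO_SHORT = "too_short"
    MISSING_GNEQ = "missing_GNEQ"
    MISSING_SEYXV = "missing_SEYxV"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ValidationResult:
    seq_id: str
    passed: bool
    reasons: tuple[FailureReason, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise DataError("passed must be equivalent to an empty reason list")


_GNEQ = compile_pattern(ACID_BASE_MOTIF)
_SEYXV = compile_pattern(NUCLEOPHILE_MOTIF)
# Relaxed acid/base alternatives seen in the family tree but excluded by
# the strict filter: G-N-D and G-S-N variants.
_RELAXED_ACID_BASE = (
    compile_pattern("G-N-E/Q/D"),
    compile_pattern("G-S-N"),
)


def validate_gh51(
    record: ProteinRecord,
    min_len: int = MIN_VALIDATION_LENGTH,
    relaxed: bool = False,
) -> ValidationResult:
    """Check family-membership criteria for one sequence.

    Passes iff the sequence has at least ``min_len`` residues AND carries
    at least one acid/base motif occurrence AND at least one nucleophile
    motif occurrence.  ``relaxed=True`` additionally accepts the G-N-D
    and G-S-N acid/base variants (sequences the strict filter would
    reject despite belonging to the family tree).
    """
    reasons: list[FailureReason] = []
    if len(record.sequence) < min_len:
        reasons.append(FailureReason.TOO_SHORT)
    if relaxed:
        acid_ok = any(scan_sequence(p, record) for p in _RELAXED_ACID_BASE)
    else:
        acid_ok = bool(scan_sequence(_GNEQ, record))
    if not acid_ok:
        reasons.append(FailureReason.MISSING_GNEQ)
    if not scan_sequence(_SEYXV, record):
        reasons.append(FailureReason.MISSING_SEYXV)
    return ValidationResult(record.id, passed=not reasons, reasons=tuple(reasons))


def filter_set(
    records: Sequence[ProteinRecord],
    min_len: int = MIN_VALIDATION_LENGTH,
    relaxed: bool = False,
) -> tuple[list[ProteinRecord], list[ValidationResult]]:
    """Partition records into (kept, excluded-with-reasons), order preserved."""
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate record ids in input set")
    kept: list[ProteinRecord] = []
    excluded: list[ValidationResult] = []
    for rec in records:
        result = validate_gh51(rec, min_len=min_len, relaxed=relaxed)
        if result.passed:
            kept.append(rec)
        else:
            excluded.append(result)
    return kept, excluded


def locate_conserved_motif(
    msa: Msa, pattern: MotifPattern, min_fraction: float = 0.5
) -> Optional[tuple[int, int]]:
    """Find the alignment-column window where a motif is conserved.

    A row matches a window of ``len(pattern)`` consecutive columns iff the
    row is gap-free there and the residues satisfy the pattern.  Among
    windows matched by at least ``min_fraction`` of rows, the one with
    the highest match fraction wins (leftmost on ties).  Returns a
    half-open column interval or ``None``.
    """
    L = len(pattern)
    if L > msa.n_cols:
        raise DataError(
            f"pattern {pattern.name!r} ({L} columns) longer than alignment ({msa.n_cols})"
        )
    best: Optional[tuple[int, int]] = None
    best_frac = 0.0
    rows = msa.rows
    for c in range(msa.n_cols - L + 1):
        n_match = 0
        for _, s in rows:
            window = s[c : c + L]
            if "-" in window:
                continue
            if pattern.matches_at(window, 0):
                n_match += 1
        frac = n_match / len(rows)
        if frac >= min_fraction and frac > best_frac:
            best = (c, c + L)
            best_frac = frac
    return best


class CatalyticStatus(enum.Enum):
    CANONICAL_E = "canonical_E"
    SUBSTITUTED_Q = "substituted_Q"
    SUBSTITUTED_D = "substituted_D"
    VARIANT_GSN = "variant_GSN"
    UNDETERMINED = "undetermined"

    def __str__(self) -> str:
        return self.value


class Evidence(enum.Enum):
    DIRECT_SCAN = "direct_scan"
    ALIGNMENT_COLUMN = "alignment_column"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class CatalyticCall:
    seq_id: str
    status: CatalyticStatus
    motif_start: Optional[int] = None
    evidence: Optional[Evidence] = None


# Direct-scan precedence: canonical acid/base first, then the known
# substitutions, then the G-S-N variant.
_CATALYTIC_LADDER: tuple[tuple[str, CatalyticStatus], ...] = (
    ("G-N-E", CatalyticStatus.CANONICAL_E),
    ("G-N-Q", CatalyticStatus.SUBSTITUTED_Q),
    ("G-N-D", CatalyticStatus.SUBSTITUTED_D),
    ("G-S-N", CatalyticStatus.VARIANT_GSN),
)
_CATALYTIC_PATTERNS = {text: compile_pattern(text) for text, _ in _CATALYTIC_LADDER}

_COLUMN_STATUS = {
    "E": CatalyticStatus.CANONICAL_E,
    "Q": CatalyticStatus.SUBSTITUTED_Q,
    "D": CatalyticStatus.SUBSTITUTED_D,
}


def classify_catalytic(
    record: ProteinRecord,
    msa: Optional[Msa] = None,
    ref_column: Optional[int] = None,
) -> CatalyticCall:
    """Classify the catalytic acid/base position of one sequence.

    Without alignment evidence, scans directly for G-N-E, then G-N-Q,
    then G-N-D, then G-S-N; the first motif with any occurrence decides
    the status (leftmost occurrence reported; multiple occurrences of the
    deciding motif are logged as ambiguous).  When both ``msa`` and the
    reference acid/base column ``ref_column`` are given, the call is made
    from the residue of this sequence in that column instead
    (E/Q/D mapped to their statuses, anything else undetermined).
    """
    if msa is not None and ref_column is not None:
        row = msa.row(record.id)
        if not 0 <= ref_column < msa.n_cols:
            raise DataError(f"reference column {ref_column} out of range")
        ch = row[ref_column]
        status = _COLUMN_STATUS.get(ch, CatalyticStatus.UNDETERMINED)
        res_idx = msa.residue_index_of(record.id, ref_column)
        motif_start = None
        if status is not CatalyticStatus.UNDETERMINED and res_idx is not None and res_idx >= 2:
            # acid/base residue is position 3 of the G-N-E style motif
            motif_start = res_idx - 2
        return CatalyticCall(record.id, status, motif_start, Evidence.ALIGNMENT_COLUMN)

    for text, status in _CATALYTIC_LADDER:
        hits = scan_sequence(_CATALYTIC_PATTERNS[text], record)
        if hits:
            if len(hits) > 1:
                logger.warning(
                    "record %s: %d occurrences of %s; leftmost used (ambiguous)",
                    record.id, len(hits), text,
                )
            return CatalyticCall(record.id, status, hits[0].start, Evidence.DIRECT_SCAN)
    return CatalyticCall(record.id, CatalyticStatus.UNDETERMINED)


def write_validation_report(path, results: Iterable[tuple[ProteinRecord, ValidationResult]]) -> None:
    """TSV report: id, length, passed, comma-joined reasons."""
    with open(path, "w") as fh:
        fh.write("id\tlength\tpassed\treasons\n")
        for rec, res in results:
            reasons = ",".join(str(r) for r in res.reasons)
            fh.write(f"{rec.id}\t{len(rec)}\t{str(res.passed).lower()}\t{reasons}\n")


def write_catalytic_report(path, calls: Iterable[CatalyticCall]) -> None:
    """TSV report: id, status, motif_start (1-based in report), evidence."""
    with open(path, "w") as fh:
        fh.write("id\tstatus\tmotif_start\tevidence\n")
        for call in calls:
            start = "" if call.motif_start is None else str(call.motif_start + 1)
            evidence = "" if call.evidence is None else str(call.evidence)
            fh.write(f"{call.seq_id}\t{call.status}\t{start}\t{evidence}\n")
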