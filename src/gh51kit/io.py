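"""Sequence and alignment I/O with coordinate bookkeeping.

Supported formats: multi-record FASTA, aligned FASTA ("afa") and
Stockholm 1.0 (sequence lines only; ``#=GC``/``#=GR`` annotation is
ignored on read).  All coordinates are 0-based, half-open.

The residue alphabet is the 20 canonical amino acids plus ``X``;
ambiguity codes B/Z/U/O are mapped to ``X`` with a logged warning.
Both ``-`` and ``.`` are accepted as gap characters on input; ``-`` is
emitted on output.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DataError, ParseError

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "X"
_AMBIGUOUS = {"B": "X", "Z": "X", "U": "X", "O": "X"}
GAP = "-"


class Group(enum.Enum):
    """Taxonomic group label for prevalence aggregation."""

    PLANT = "plant"
    BACTERIA = "bacteria"
    FUNGI = "fungi"
    INSECT = "insect"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # report-friendly
        return self.value


def clean_sequence(raw: str, *, where: str = "") -> str:
    """Uppercase, strip ``*`` stops, map ambiguity codes to X, validate."""
    seq = raw.upper().replace("*", "")
    mapped = []
    for ch in seq:
        if ch in _AMBIGUOUS:
            logger.warning("ambiguous residue %r mapped to X%s", ch, f" ({where})" if where else "")
            ch = "X"
        if ch not in ALPHABET:
            raise ParseError(f"illegal residue character {ch!r}{f' ({where})' if where else ''}")
        mapped.append(ch)
    return "".join(mapped)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with identity, description and group label.

    The sequence is gap-free, non-empty, and drawn from the 20-letter
    amino-acid alphabet plus X.
    """

    id: str
    sequence: str
    description: str = ""
    group: Group = Group.UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("record id must be non-empty")
        if not self.sequence:
            raise DataError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise DataError(
                f"record {self.id!r}: illegal residue characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into :class:`ProteinRecord` objects.

    Stop characters ``*`` are stripped and lowercase residues uppercased.
    Raises :class:`ParseError` naming the line number for malformed
    headers, illegal residues and duplicate ids.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    cur_chunks: list[str] = []
    cur_line = 0

    def flush() -> None:
        if cur_id is None:
            return
        seq = "".join(cur_chunks)
        if not seq:
            raise ParseError(f"line {cur_line}: record {cur_id!r} has no sequence")
        records.append(ProteinRecord(cur_id, seq, cur_desc))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                parts = header.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                if cur_id in seen:
                    raise ParseError(f"line {lineno}: duplicate id {cur_id!r}")
                seen.add(cur_id)
                cur_chunks = []
                cur_line = lineno
            else:
                if cur_id is None:
                    raise ParseError(f"line {lineno}: sequence data before first header")
                try:
                    cur_chunks.append(clean_sequence(line.strip()))
                except ParseError as exc:
                    raise ParseError(f"line {lineno}: {exc}") from None
    flush()
    return records


def write_fasta(path: str | Path, records: Iterable[ProteinRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


class Msa:
    """A column-indexed multiple sequence alignment.

    Rows are ``(id, aligned string)`` pairs of identical length.  Gap
    characters are normalized to ``-``.  Per-row coordinate maps between
    alignment columns and ungapped residue indices are built eagerly and
    are mutually inverse on non-gap positions.
    """

    def __init__(self, rows: Sequence[tuple[str, str]]):
        if not rows:
            raise DataError("alignment must contain at least one row")
        norm: list[tuple[str, str]] = []
        for rid, aligned in rows:
            s = aligned.upper().replace(".", GAP)
            cleaned = []
            for ch in s:
                if ch == GAP:
                    cleaned.append(ch)
                    continue
                if ch in _AMBIGUOUS:
                    ch = "X"
                if ch not in ALPHABET:
                    raise ParseError(f"row {rid!r}: illegal residue character {ch!r}")
                cleaned.append(ch)
            norm.append((rid, "".join(cleaned)))
        lengths = {len(s) for _, s in norm}
        if len(lengths) != 1:
            ragged = sorted({rid for rid, s in norm})
            raise DataError(f"ragged alignment rows: {ragged}")
        ids = [rid for rid, _ in norm]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate row ids: {dupes}")

        self._rows = norm
        self._index = {rid: i for i, (rid, _) in enumerate(norm)}
        self.n_cols = lengths.pop()
        self.n_rows = len(norm)
        # col -> residue index (None on gaps); residue index -> col
        self._col2res: dict[str, list[int | None]] = {}
        self._res2col: dict[str, list[int]] = {}
        for rid, s in norm:
            c2r: list[int | None] = []
            r2c: list[int] = []
            k = 0
            for c, ch in enumerate(s):
                if ch == GAP:
                    c2r.append(None)
                else:
                    c2r.append(k)
                    r2c.append(c)
                    k += 1
            self._col2res[rid] = c2r
            self._res2col[rid] = r2c

    # -- basic access ---------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self._rows]

    @property
    def rows(self) -> list[tuple[str, str]]:
        return list(self._rows)

    def row(self, rid: str) -> str:
        if rid not in self._index:
            raise DataError(f"unknown alignment row id {rid!r}")
        return self._rows[self._index[rid]][1]

    def ungap(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def column(self, c: int) -> str:
        return "".join(s[c] for _, s in self._rows)

    def gap_fraction(self, c: int) -> float:
        col = self.column(c)
        return col.count(GAP) / len(col)

    # -- coordinate maps ------------------------------------------------
    def residue_index_of(self, rid: str, col: int) -> int | None:
        """Ungapped residue index at ``col``, or None if the row is gapped there."""
        self.row(rid)
        return self._col2res[rid][col]

    def column_of(self, rid: str, res_index: int) -> int:
        """Alignment column holding the row's ``res_index``-th residue."""
        self.row(rid)
        return self._res2col[rid][res_index]

    # -- derived alignments --------------------------------------------
    def take_columns(self, cols: Sequence[int]) -> "Msa":
        """New alignment from the given columns, in the given order."""
        return Msa([(rid, "".join(s[c] for c in cols)) for rid, s in self._rows])

    def take_rows(self, rids: Sequence[str]) -> "Msa":
        return Msa([(rid, self.row(rid)) for rid in rids])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Msa) and self._rows == other._rows

    def __repr__(self) -> str:
        return f"Msa(n_rows={self.n_rows}, n_cols={self.n_cols})"


def read_alignment(path: str | Path, format: str = "afa") -> Msa:
    """Read an alignment in aligned-FASTA or Stockholm format."""
    if format == "afa":
        rows: list[tuple[str, str]] = []
        seen: set[str] = set()
        cur_id: str | None = None
        chunks: list[str] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n\r")
                if not line.strip():
                    continue
                if line.startswith(">"):
                    if cur_id is not None:
                        rows.append((cur_id, "".join(chunks)))
                    header = line[1:].strip()
                    if not header:
                        raise ParseError(f"line {lineno}: empty FASTA header")
                    cur_id = header.split(None, 1)[0]
                    if cur_id in seen:
                        raise ParseError(f"line {lineno}: duplicate id {cur_id!r}")
                    seen.add(cur_id)
                    chunks = []
                else:
                    if cur_id is None:
                        raise ParseError(f"line {lineno}: sequence data before first header")
                    chunks.append(line.strip())
        if cur_id is not None:
            rows.append((cur_id, "".join(chunks)))
        if not rows:
            raise ParseError(f"{path}: no alignment rows found")
        return Msa(rows)
    if format == "stockholm":
        return _read_stockholm(path)
    raise DataError(f"unknown alignment format {format!r}")


def _read_stockholm(path: str | Path) -> Msa:
    order: list[str] = []
    parts: dict[str, list[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# STOCKHOLM"):
            raise ParseError("line 1: missing '# STOCKHOLM' header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n\r")
            if not line.strip() or line.startswith("#"):
                continue
            if line.strip() == "//":
                break
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(f"line {lineno}: expected 'name sequence', got {line!r}")
            name, seq = fields
            if name not in parts:
                order.append(name)
                parts[name] = []
            parts[name].append(seq)
    if not order:
        raise ParseError(f"{path}: no alignment rows found")
    return Msa([(name, "".join(parts[name])) for name in order])


def write_alignment(path: str | Path, msa: Msa, format: str = "afa", width: int = 60) -> None:
    if format == "afa":
        with open(path, "w") as fh:
            for rid, s in msa.rows:
                fh.write(f">{rid}\n")
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")
    elif format == "stockholm":
        name_w = max(len(rid) for rid, _ in msa.rows)
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            for rid, s in msa.rows:
                fh.write(f"{rid:<{name_w}} {s}\n")
            fh.write("//\n")
    else:
        raise DataError(f"unknown alignment format {format!r}")


@dataclass
class GroupTable:
    """Mapping from sequence id to taxonomic group, with provenance notes."""

    groups: dict[str, Group] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def group(self, rid: str) -> Group:
        return self.groups.get(rid, Group.UNKNOWN)

    @classmethod
    def read(cls, path: str | Path) -> "GroupTable":
        """Read a TSV with header ``id<TAB>group`` (optional third provenance column)."""
        table = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n\r").split("\t")
            if header[:2] != ["id", "group"]:
                raise ParseError("line 1: expected header 'id\\tgroup'")
            for lineno, line in enumerate(fh, 2):
                line = line.rstrip("\n\r")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(f"line {lineno}: expected at least 2 tab-separated fields")
                rid, group_name = fields[0], fields[1]
                if rid in table.groups:
                    raise ParseError(f"line {lineno}: duplicate id {rid!r}")
                try:
                    table.groups[rid] = Group(group_name)
                except ValueError:
                    raise ParseError(f"line {lineno}: unknown group {group_name!r}") from None
                if len(fields) > 2:
                    table.provenance[rid] = fields[2]
        return table

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tgroup\tprovenance\n")
            for rid in self.groups:
                fh.write(f"{rid}\t{self.groups[rid].value}\t{self.provenance.get(rid, '')}\n")
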