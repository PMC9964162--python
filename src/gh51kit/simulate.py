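"""Synthetic protein-family generator with exact ground truth.

Builds an ancestor sequence carrying the catalytic motifs (acid/base
G-N-E and nucleophile S-E-Y-x-V) and, optionally, an N-terminal domain
bracketed by the L-x-V-D / S-x-x-P anchors with the internal
G-x-x-F-E-x-I-x-x-x-G-x-G-G motif.  Family members are derived by point
substitutions (planted motif positions protected, except the catalytic
variants the truth table plants) and geometric-length indels that never
fall inside a motif.  Decoys are residue-shuffled family members.  A
true alignment is emitted from the known indel history, and every truth
label is re-checked against the emitted sequences at generation time.

The ancestor is sanitized so that no pipeline motif occurs anywhere
except at its planted site; with zero noise, downstream motif scans
therefore agree with the truth table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DataError
from .io import AA20, Group, Msa, ProteinRecord
from .motifs import (
    ACID_BASE_MOTIF,
    DOMAIN_CORE_MOTIF,
    DOMAIN_END_MOTIF,
    DOMAIN_START_MOTIF,
    NUCLEOPHILE_MOTIF,
    CatalyticStatus,
    compile_pattern,
    scan_string,
    validate_gh51,
)

_STATUS_SITE = {
    CatalyticStatus.CANONICAL_E: "GNE",
    CatalyticStatus.SUBSTITUTED_Q: "GNQ",
    CatalyticStatus.SUBSTITUTED_D: "GND",
    CatalyticStatus.VARIANT_GSN: "GSN",
}

# every motif the pipeline scans for, mapped to the ancestor element
# allowed to carry it; the sanitizer removes occurrences anywhere else
_PATTERN_SITES: dict[str, str] = {
    DOMAIN_START_MOTIF: "anchor_start",
    DOMAIN_END_MOTIF: "anchor_end",
    NUCLEOPHILE_MOTIF: "nucleophile",
    "G-N-E": "acid_base",
    "G-N-Q": "acid_base",
    "G-N-D": "acid_base",
    "G-S-N": "acid_base",
}
_ALL_PATTERNS = {text: compile_pattern(text) for text in _PATTERN_SITES}


@dataclass
class SimParams:
    """Knobs of the generator; ``seed`` is mandatory."""

    seed: int
    n: int = 50
    group: Group = Group.PLANT
    length_range: tuple[int, int] = (350, 700)
    domain_prevalence: float = 1.0
    catalytic_composition: dict[CatalyticStatus, float] = field(
        default_factory=lambda: {CatalyticStatus.CANONICAL_E: 1.0}
    )
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    decoy_fraction: float = 0.0
    id_prefix: str = "seq"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError("n must be at least 1")
        for name, v in (
            ("domain_prevalence", self.domain_prevalence),
            ("substitution_rate", self.substitution_rate),
            ("indel_rate", self.indel_rate),
            ("decoy_fraction", self.decoy_fraction),
        ):
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1]")
        total = sum(self.catalytic_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError("catalytic composition must sum to 1")
        if self.length_range[0] > self.length_range[1]:
            raise DataError("invalid length range")


@dataclass(frozen=True)
class TruthRow:
    id: str
    group: Group
    is_decoy: bool
    has_domain: bool
    domain_start: Optional[int]  # 0-based half-open, ungapped coordinates
    domain_end: Optional[int]
    catalytic_status: Optional[CatalyticStatus]
    passes_filter: bool


@dataclass
class TruthTable:
    rows: list[TruthRow]

    def by_id(self) -> dict[str, TruthRow]:
        return {r.id: r for r in self.rows}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "id\tgroup\tis_decoy\thas_domain\tdomain_start\tdomain_end\t"
                "catalytic_status\tpasses_filter\n"
            )
            for r in self.rows:
                fh.write(
                    f"{r.id}\t{r.group}\t{int(r.is_decoy)}\t{int(r.has_domain)}\t"
                    f"{'' if r.domain_start is None else r.domain_start}\t"
                    f"{'' if r.domain_end is None else r.domain_end}\t"
                    f"{'' if r.catalytic_status is None else r.catalytic_status}\t"
                    f"{int(r.passes_filter)}\n"
                )


def _random_residues(rng: np.random.Generator, k: int) -> list[str]:
    return [AA20[i] for i in rng.integers(0, 20, size=k)]


def _realize(rng: np.random.Generator, text: str) -> list[str]:
    """Instantiate a motif string, drawing wildcards/alternations at random."""
    out = []
    for tok in text.split("-"):
        if tok == "x":
            out.append(AA20[rng.integers(0, 20)])
        else:
            choices = tok.split("/")
            out.append(choices[rng.integers(0, len(choices))])
    return out


class _Ancestor:
    """Ancestor sequence plus the coordinates of every planted element."""

    def __init__(self, rng: np.random.Generator, params: SimParams):
        lo, hi = params.length_range
        target = int(rng.integers(lo, hi + 1))

        parts: list[tuple[str, list[str]]] = []
        parts.append(("pre", _random_residues(rng, 8)))
        parts.append(("anchor_start", _realize(rng, DOMAIN_START_MOTIF)))
        parts.append(("body1", _random_residues(rng, 30)))
        parts.append(("core", _realize(rng, DOMAIN_CORE_MOTIF)))
        parts.append(("body2", _random_residues(rng, 30)))
        parts.append(("anchor_end", _realize(rng, DOMAIN_END_MOTIF)))
        parts.append(("linker", _random_residues(rng, 40)))
        parts.append(("acid_base", list("GNE")))
        parts.append(("mid", _random_residues(rng, 30)))
        parts.append(("nucleophile", _realize(rng, NUCLEOPHILE_MOTIF)))
        fixed_len = sum(len(p) for _, p in parts)
        if target < fixed_len:
            raise DataError(
                f"length range infeasible: need at least {fixed_len} residues "
                f"for the planted elements"
            )
        parts.append(("tail", _random_residues(rng, target - fixed_len)))

        self.spans: dict[str, tuple[int, int]] = {}
        residues: list[str] = []
        for name, chunk in parts:
            self.spans[name] = (len(residues), len(residues) + len(chunk))
            residues.extend(chunk)
        self.residues = residues
        self.length = len(residues)
        self.domain_span = (self.spans["anchor_start"][0], self.spans["anchor_end"][1])
        # protected from substitution/sanitation: the *fixed* token
        # positions of the planted motifs (wildcard positions may mutate
        # freely without breaking a motif)
        motif_texts = {
            "anchor_start": DOMAIN_START_MOTIF,
            "core": DOMAIN_CORE_MOTIF,
            "anchor_end": DOMAIN_END_MOTIF,
            "acid_base": "G-N-E",
            "nucleophile": NUCLEOPHILE_MOTIF,
        }
        self.protected: set[int] = set()
        for name, text in motif_texts.items():
            start = self.spans[name][0]
            for off, tok in enumerate(compile_pattern(text).tokens):
                if tok is not None:
                    self.protected.add(start + off)
        # indels must not split any planted motif
        self.motif_spans = [self.spans[name] for name in motif_texts]
        self._sanitize(rng)

    def _sanitize(self, rng: np.random.Generator) -> None:
        """Rewrite accidental motif occurrences outside the planted sites."""
        for _ in range(10000):
            seq = "".join(self.residues)
            dirty = False
            for text, pat in _ALL_PATTERNS.items():
                allowed_start = self.spans[_PATTERN_SITES[text]][0]
                for hit in scan_string(pat, seq):
                    if hit.start == allowed_start:
                        continue
                    # mutate one non-protected fixed-token position of the hit
                    positions = [
                        hit.start + off
                        for off, tok in enumerate(pat.tokens)
                        if tok is not None and (hit.start + off) not in self.protected
                    ]
                    if not positions:  # overlaps a planted motif entirely
                        continue
                    pos = positions[int(rng.integers(0, len(positions)))]
                    old = self.residues[pos]
                    choices = [aa for aa in AA20 if aa != old]
                    self.residues[pos] = choices[int(rng.integers(0, 19))]
                    dirty = True
            if not dirty:
                return
        raise DataError("sanitizer failed to converge")


# MSA column keys: (ancestor position, 0) for inherited columns, and
# (p, 1, member index, j) for the j-th residue inserted after position p.
_AncKey = tuple[int, int, int, int]


def generate_family(params: SimParams) -> tuple[list[ProteinRecord], Msa, TruthTable]:
    """Generate one labeled family: records, true alignment, truth table.

    The alignment covers family members only (decoys are unalignable by
    construction).  Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    anc = _Ancestor(rng, params)
    n_decoys = int(round(params.decoy_fraction * params.n))
    n_family = params.n - n_decoys
    if n_family < 1:
        raise DataError("decoy fraction leaves no family members")

    statuses = list(_STATUS_SITE)
    probs = np.array([params.catalytic_composition.get(s, 0.0) for s in statuses])
    member_status = [
        statuses[i] for i in rng.choice(len(statuses), size=n_family, p=probs / probs.sum())
    ]
    member_domain = rng.random(n_family) < params.domain_prevalence

    dom_s, dom_e = anc.domain_span
    acid_s = anc.spans["acid_base"][0]

    rows: list[tuple[str, dict[_AncKey, str]]] = []
    insert_keys: set[_AncKey] = set()
    records: list[ProteinRecord] = []
    truth_rows: list[TruthRow] = []

    for m in range(n_family):
        rid = f"{params.id_prefix}{m:04d}"
        residues = list(anc.residues)
        # plant the catalytic variant
        for off, ch in enumerate(_STATUS_SITE[member_status[m]]):
            residues[acid_s + off] = ch
        # point substitutions outside protected positions
        if params.substitution_rate > 0:
            hits = np.nonzero(rng.random(anc.length) < params.substitution_rate)[0]
            for p in hits:
                if int(p) in anc.protected:
                    continue
                old = residues[p]
                choices = [aa for aa in AA20 if aa != old]
                residues[p] = choices[int(rng.integers(0, 19))]
        # indels
        has_domain = bool(member_domain[m])
        deleted: set[int] = set()
        insertions: dict[int, list[str]] = {}
        if params.indel_rate > 0:
            starts = np.nonzero(rng.random(anc.length) < params.indel_rate)[0]
            for p in starts:
                p = int(p)
                length = int(rng.geometric(0.5))
                if rng.random() < 0.5:  # deletion of [p, p+length)
                    q = min(p + length, anc.length)
                    if p >= q or any(p < e and s < q for s, e in anc.motif_spans):
                        continue
                    deleted |= set(range(p, q))
                else:  # insertion after position p; must not split a motif
                    if any(s <= p < e - 1 for s, e in anc.motif_spans):
                        continue
                    # a domain-less member must stay all-gap inside the
                    # domain window of the true alignment
                    if not has_domain and dom_s <= p < dom_e:
                        continue
                    insertions.setdefault(p, []).extend(
                        _random_residues(rng, length)
                    )
        if not has_domain:
            deleted |= set(range(dom_s, dom_e))

        cells: dict[_AncKey, str] = {}
        seq_chars: list[str] = []
        final_index: dict[int, int] = {}  # ancestor position -> final residue index
        for p in range(anc.length):
            key = (p, 0, 0, 0)
            if p in deleted:
                cells[key] = "-"
            else:
                final_index[p] = len(seq_chars)
                cells[key] = residues[p]
                seq_chars.append(residues[p])
            for j, ch in enumerate(insertions.get(p, [])):
                ikey = (p, 1, m, j)
                insert_keys.add(ikey)
                cells[ikey] = ch
                seq_chars.append(ch)
        sequence = "".join(seq_chars)

        domain_start = final_index[dom_s] if has_domain else None
        domain_end = final_index[dom_e - 1] + 1 if has_domain else None
        record = ProteinRecord(rid, sequence, group=params.group)
        records.append(record)
        rows.append((rid, cells))
        truth_rows.append(
            TruthRow(
                id=rid,
                group=params.group,
                is_decoy=False,
                has_domain=has_domain,
                domain_start=domain_start,
                domain_end=domain_end,
                catalytic_status=member_status[m],
                passes_filter=validate_gh51(record).passed,
            )
        )

    # decoys: residue-shuffled copies of fresh family-like sequences
    for d in range(n_decoys):
        rid = f"{params.id_prefix}d{d:03d}"
        shuffled = "".join(
            np.array(list(anc.residues))[rng.permutation(anc.length)]
        )
        record = ProteinRecord(rid, shuffled, group=params.group)
        records.append(record)
        truth_rows.append(
            TruthRow(
                id=rid,
                group=params.group,
                is_decoy=True,
                has_domain=False,
                domain_start=None,
                domain_end=None,
                catalytic_status=None,
                passes_filter=validate_gh51(record).passed,
            )
        )

    # assemble the true alignment over the global column key set
    anc_keys: list[_AncKey] = [(p, 0, 0, 0) for p in range(anc.length)]
    all_keys = sorted(anc_keys + sorted(insert_keys))
    aligned_rows = [
        (rid, "".join(cells.get(k, "-") for k in all_keys)) for rid, cells in rows
    ]
    msa = Msa(aligned_rows)

    truth = TruthTable(truth_rows)
    _check_consistency(records, msa, truth)
    return records, msa, truth


def _check_consistency(records, msa: Msa, truth: TruthTable) -> None:
    """Generation-time audit: truth labels match the emitted sequences."""
    by_id = {r.id: r for r in records}
    start_pat = compile_pattern(DOMAIN_START_MOTIF)
    end_pat = compile_pattern(DOMAIN_END_MOTIF)
    for row in truth.rows:
        seq = by_id[row.id].sequence
        if row.has_domain:
            assert row.domain_start is not None and row.domain_end is not None
            assert start_pat.matches_at(seq, row.domain_start), row.id
            assert end_pat.matches_at(seq, row.domain_end - len(end_pat)), row.id
        if not row.is_decoy:
            assert msa.ungap(row.id) == seq, row.id


def write_params_json(path, params: SimParams) -> None:
    import json

    payload = {
        "seed": params.seed,
        "n": params.n,
        "group": str(params.group),
        "length_range": list(params.length_range),
        "domain_prevalence": params.domain_prevalence,
        "catalytic_composition": {
            str(k): v for k, v in params.catalytic_composition.items()
        },
        "substitution_rate": params.substitution_rate,
        "indel_rate": params.indel_rate,
        "decoy_fraction": params.decoy_fraction,
        "id_prefix": params.id_prefix,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
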