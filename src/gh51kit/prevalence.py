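"""Per-group domain prevalence statistics from scan results.

Percentages are rounded half-up to one decimal (the reporting style of
the source counts, e.g. 119/133 -> 89.5).  Confidence intervals are
Wilson score intervals at 95%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from scipy.stats import norm

from .errors import DataError
from .hmm import HmmHit
from .io import Group, GroupTable


def percent(n_hit: int, n_total: int) -> float:
    """``100 * n_hit / n_total`` rounded half-up to one decimal."""
    if n_total <= 0:
        raise DataError("n_total must be positive")
    if not 0 <= n_hit <= n_total:
        raise DataError("n_hit must lie in [0, n_total]")
    value = Decimal(100) * Decimal(n_hit) / Decimal(n_total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def wilson_ci(n_hit: int, n_total: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for the hit proportion, as percentages."""
    if n_total <= 0:
        raise DataError("n_total must be positive")
    z = float(norm.ppf(0.5 + conf / 2))
    p = n_hit / n_total
    denom = 1 + z * z / n_total
    center = (p + z * z / (2 * n_total)) / denom
    half = (z / denom) * ((p * (1 - p) / n_total + z * z / (4 * n_total**2)) ** 0.5)
    lo = max(0.0, center - half)
    hi = min(1.0, center + half)
    return (100 * lo, 100 * hi)


@dataclass(frozen=True)
class PrevalenceRow:
    group: Group
    n_total: int
    n_hit: int
    percent: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PrevalenceTable:
    rows: tuple[PrevalenceRow, ...]

    def row(self, group: Group) -> PrevalenceRow:
        for r in self.rows:
            if r.group is group:
                return r
        raise DataError(f"no prevalence row for group {group}")


def prevalence_table(hits: Sequence[HmmHit], groups: GroupTable) -> PrevalenceTable:
    """Aggregate scanned hits per group.

    Only scanned sequences enter the denominators; skipped (short)
    sequences must not be in ``hits``.  Groups appear in the fixed enum
    order, only if present among the hits.
    """
    totals: dict[Group, int] = {}
    positive: dict[Group, int] = {}
    for hit in hits:
        g = groups.group(hit.seq_id)
        totals[g] = totals.get(g, 0) + 1
        positive[g] = positive.get(g, 0) + (1 if hit.passed else 0)
    rows = []
    for g in Group:
        if g not in totals:
            continue
        n_tot, n_hit = totals[g], positive[g]
        lo, hi = wilson_ci(n_hit, n_tot)
        rows.append(PrevalenceRow(g, n_tot, n_hit, percent(n_hit, n_tot), lo, hi))
    return PrevalenceTable(tuple(rows))


def write_prevalence_tsv(path, table: PrevalenceTable) -> None:
    with open(path, "w") as fh:
        fh.write("group\tn_total\tn_hit\tpercent\tci95_low\tci95_high\n")
        for r in table.rows:
            fh.write(
                f"{r.group}\t{r.n_total}\t{r.n_hit}\t{r.percent}\t{r.ci_low:.2f}\t{r.ci_high:.2f}\n"
            )


def write_prevalence_json(path, table: PrevalenceTable) -> None:
    payload = [
        {
            "group": str(r.group),
            "n_total": r.n_total,
            "n_hit": r.n_hit,
            "percent": r.percent,
            "ci95": [round(r.ci_low, 4), round(r.ci_high, 4)],
        }
        for r in table.rows
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
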