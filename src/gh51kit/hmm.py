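"""Profile hidden Markov model: build from an alignment, score sequences.

A native stand-in for hmmbuild/hmmscan.  The model is a classic
match/insert/delete profile:

* match states ``M1..Mm`` with per-state emission distributions over the
  20 canonical residues; ``X`` scores as background (log-odds 0);
* insert states ``I1..Im-1`` emitting the background distribution;
* delete states ``D2..Dm`` (silent);
* core transitions ``Mk -> {Mk+1, Ik, Dk+1}``, ``Ik -> {Mk+1, Ik}``,
  ``Dk -> {Mk+1, Dk+1}`` estimated from the training alignment rows with
  pseudocount smoothing and uniform per-row weights (so duplicated rows
  do not change the profile).

Scoring is log-odds against an i.i.d. background null with a geometric
length term: flanking residues outside the aligned core cost exactly
zero, while every core-emitted residue receives a small ``-log(eta)``
length-correction bonus.  In the default **local** mode the model enters
any match state with probability ``1/M`` and exits any match state
``k < M`` with probability ``tau`` (continuation scaled by ``1 - tau``);
``M_m`` and ``D_m`` exit with probability 1.  In **glocal** mode entry is
only at ``M1`` and exit only from ``M_m``/``D_m``.

Scores are reported in bits:
``log2 sum_paths entry * transitions * prod(emission/background) / eta^n_core * exit``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DataError
from .io import AA20, Msa, ProteinRecord

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}
_NEG_INF = -np.inf

DEFAULT_ETA = 0.99
DEFAULT_TAU = 0.1
DEFAULT_SCAN_MIN_LEN = 200
# Raw forward bits of an unrelated full-length protein against a domain
# profile sit around +5..+11 (the summed-entry local mode picks up chance
# similarity), while genuine domain hits score in the hundreds.  The
# default acceptance threshold therefore sits well above chance but far
# below any real hit.
DEFAULT_SCAN_THRESHOLD = 25.0


@dataclass
class ProfileHmm:
    """Estimated profile parameters (probability space).

    Arrays are indexed by match-state position ``k`` in ``1..M``; index 0
    is unused padding.  Transition arrays hold the distribution leaving
    position ``k`` (valid for ``k = 1..M-1``).
    """

    M: int
    mat: np.ndarray  # (M+1, 20) match emissions
    bg: np.ndarray  # (20,) background / insert emissions
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    eta: float = DEFAULT_ETA
    tau: float = DEFAULT_TAU
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.M < 1:
            raise DataError("profile must have at least one match state")
        if not np.all(self.mat[1:] > 0) or not np.all(self.bg > 0):
            raise DataError("all emission probabilities must be positive")
        if not np.allclose(self.mat[1:].sum(axis=1), 1.0, atol=1e-9):
            raise DataError("match emission rows must sum to 1")
        if abs(self.bg.sum() - 1.0) > 1e-9:
            raise DataError("background must sum to 1")
        for k in range(1, self.M):
            for name, total in (
                ("M", self.t_mm[k] + self.t_mi[k] + self.t_md[k]),
                ("I", self.t_im[k] + self.t_ii[k]),
                ("D", self.t_dm[k] + self.t_dd[k]),
            ):
                if abs(total - 1.0) > 1e-9:
                    raise DataError(f"outgoing {name} distribution at {k} sums to {total}")


def select_match_columns(msa: Msa, max_gap_fraction: float = 0.5) -> list[bool]:
    """Flag alignment columns as match states by gap fraction.

    A column is a match column iff its gap fraction is at most
    ``max_gap_fraction``.  Raises if no column qualifies.
    """
    flags = [msa.gap_fraction(c) <= max_gap_fraction for c in range(msa.n_cols)]
    if not any(flags):
        raise DataError("no match columns at this gap-fraction threshold")
    return flags


def build_profile(
    msa: Msa,
    pseudocount: float = 1.0,
    background: str = "uniform",
    max_gap_fraction: float = 0.5,
    eta: float = DEFAULT_ETA,
    tau: float = DEFAULT_TAU,
) -> ProfileHmm:
    """Estimate a :class:`ProfileHmm` from an alignment.

    Rows are uniformly weighted ``1/n_rows`` so the profile is invariant
    to duplicating rows.  Match emissions are
    ``(weighted counts + pseudocount * background) / (weight + pseudocount)``;
    transitions get ``pseudocount / n_options`` added per option.
    """
    if pseudocount <= 0:
        raise DataError("pseudocount must be positive")
    flags = select_match_columns(msa, max_gap_fraction)
    mcols = [c for c, f in enumerate(flags) if f]
    M = len(mcols)
    w = 1.0 / msa.n_rows

    if background == "uniform":
        bg = np.full(20, 1.0 / 20)
    elif background == "from_alignment":
        counts = np.ones(20)  # Laplace floor keeps every residue possible
        for _, s in msa.rows:
            for ch in s:
                if ch in _AA_INDEX:
                    counts[_AA_INDEX[ch]] += 1
        bg = counts / counts.sum()
    else:
        raise DataError(f"unknown background mode {background!r}")

    emit_counts = np.zeros((M + 1, 20))
    emit_totals = np.zeros(M + 1)
    # transition counts from position k (1..M-1)
    c_mm = np.zeros(M + 1)
    c_mi = np.zeros(M + 1)
    c_md = np.zeros(M + 1)
    c_im = np.zeros(M + 1)
    c_ii = np.zeros(M + 1)
    c_dm = np.zeros(M + 1)
    c_dd = np.zeros(M + 1)

    for rid, s in msa.rows:
        # per-position state (M or D) and insert counts between positions
        states: list[str] = []
        for k, c in enumerate(mcols, start=1):
            ch = s[c]
            states.append("D" if ch == "-" else "M")
            if ch != "-" and ch in _AA_INDEX:
                emit_counts[k, _AA_INDEX[ch]] += w
                emit_totals[k] += w
        for k in range(1, M):
            lo, hi = mcols[k - 1], mcols[k]
            n_ins = sum(
                1 for c in range(lo + 1, hi) if not flags[c] and s[c] != "-"
            )
            prev, nxt = states[k - 1], states[k]
            if prev == "M" and nxt == "M" and n_ins > 0:
                c_mi[k] += w
                c_ii[k] += w * (n_ins - 1)
                c_im[k] += w
            elif prev == "M":
                # inserts adjacent to a delete have no modeled path (no
                # D<->I transitions); attribute the transition directly.
                (c_mm if nxt == "M" else c_md)[k] += w
            else:  # prev == "D"
                (c_dm if nxt == "M" else c_dd)[k] += w

    alpha = pseudocount
    mat = np.zeros((M + 1, 20))
    mat[1:] = (emit_counts[1:] + alpha * bg) / (emit_totals[1:, None] + alpha)

    def smooth(counts: list[np.ndarray]) -> list[np.ndarray]:
        n_opt = len(counts)
        total = sum(counts)
        return [(c + alpha / n_opt) / (total + alpha) for c in counts]

    t_mm, t_mi, t_md = smooth([c_mm, c_mi, c_md])
    t_im, t_ii = smooth([c_im, c_ii])
    t_dm, t_dd = smooth([c_dm, c_dd])

    return ProfileHmm(
        M=M,
        mat=mat,
        bg=bg,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd,
        eta=eta,
        tau=tau,
        metadata={
            "n_rows": msa.n_rows,
            "n_cols": msa.n_cols,
            "match_columns": mcols,
            "pseudocount": pseudocount,
            "background": background,
            "max_gap_fraction": max_gap_fraction,
        },
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _score_tables(profile: ProfileHmm, mode: str):
    """Log-space tables folding in local exit continuation (1 - tau)."""
    if mode not in ("local", "glocal"):
        raise DataError(f"unknown alignment mode {mode!r}")
    M = profile.M
    log_eta = math.log(profile.eta)
    # match emission log-odds, with the geometric length-correction bonus
    with np.errstate(divide="ignore"):
        msc = np.full((M + 1, 21), _NEG_INF)
        msc[1:, :20] = np.log(profile.mat[1:] / profile.bg) - log_eta
        msc[1:, 20] = -log_eta  # X scores as background
        isc = -log_eta
        cont = np.zeros(M + 1)
        if mode == "local":
            cont[1 : M] = math.log1p(-profile.tau)
            entry = np.full(M + 1, -math.log(M))
            exit_m = np.full(M + 1, math.log(profile.tau) if profile.tau > 0 else _NEG_INF)
            exit_m[M] = 0.0
        else:
            entry = np.full(M + 1, _NEG_INF)
            entry[1] = 0.0
            exit_m = np.full(M + 1, _NEG_INF)
            exit_m[M] = 0.0
        a_mm = np.log(profile.t_mm) + cont
        a_mi = np.log(profile.t_mi) + cont
        a_md = np.log(profile.t_md) + cont
        a_im = np.log(profile.t_im)
        a_ii = np.log(profile.t_ii)
        a_dm = np.log(profile.t_dm)
        a_dd = np.log(profile.t_dd)
    entry[0] = _NEG_INF
    return msc, isc, entry, exit_m, (a_mm, a_mi, a_md, a_im, a_ii, a_dm, a_dd)


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(ch, 20) for ch in seq], dtype=np.intp)


def _logaddexp_f(a: float, b: float) -> float:
    # scalar log-sum-exp on plain floats (much faster than numpy scalars)
    if a == _NEG_INF:
        return b
    if b == _NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + math.log1p(math.exp(b - a))


def forward_bits(profile: ProfileHmm, record: ProteinRecord, mode: str = "local") -> float:
    """Forward log-odds score of the whole sequence, in bits."""
    seq = _encode(record.sequence)
    if seq.size == 0:
        raise DataError("cannot score an empty sequence")
    msc, isc, entry, exit_m, (a_mm, a_mi, a_md, a_im, a_ii, a_dm, a_dd) = _score_tables(
        profile, mode
    )
    M = profile.M
    amd = a_md.tolist()
    add = a_dd.tolist()
    fM = np.full(M + 1, _NEG_INF)
    fI = np.full(M + 1, _NEG_INF)
    fD = np.full(M + 1, _NEG_INF)
    total = _NEG_INF
    for x in seq:
        nM = np.full(M + 1, _NEG_INF)
        # predecessors at k-1 from the previous row, plus fresh entry
        prev = np.logaddexp(
            np.logaddexp(fM[:-1] + a_mm[:-1], fI[:-1] + a_im[:-1]),
            fD[:-1] + a_dm[:-1],
        )
        nM[1:] = msc[1:, x] + np.logaddexp(entry[1:], prev)
        nI = isc + np.logaddexp(fM + a_mi, fI + a_ii)
        nI[M] = _NEG_INF
        # silent delete chain within the same position (sequential in k)
        nm_list = nM.tolist()
        nd_list = [_NEG_INF] * (M + 1)
        d = _NEG_INF
        for k in range(2, M + 1):
            d = _logaddexp_f(nm_list[k - 1] + amd[k - 1], d + add[k - 1])
            nd_list[k] = d
        nD = np.array(nd_list)
        fM, fI, fD = nM, nI, nD
        end_i = _logsumexp_pair(_logsumexp(fM[1:] + exit_m[1:]), float(fD[M]))
        total = _logaddexp_f(total, end_i)
    return float(total / math.log(2))


def _logsumexp(values: np.ndarray) -> float:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return _NEG_INF
    m = finite.max()
    return float(m + np.log(np.exp(finite - m).sum()))

def _logsumexp_pair(a: float, b: float) -> float:
    if a == _NEG_INF:
        return b
    if b == _NEG_INF:
        return a
    return float(np.logaddexp(a, b))


@dataclass(frozen=True)
class ViterbiResult:
    path: tuple[str, ...]
    bits: float
    interval: tuple[int, int]  # 0-based half-open residue interval of the core


def viterbi(profile: ProfileHmm, record: ProteinRecord, mode: str = "local") -> ViterbiResult:
    """Best single state path, its score in bits, and the core interval."""
    seq = _encode(record.sequence)
    if seq.size == 0:
        raise DataError("cannot score an empty sequence")
    msc, isc, entry, exit_m, (a_mm, a_mi, a_md, a_im, a_ii, a_dm, a_dd) = _score_tables(
        profile, mode
    )
    M = profile.M
    L = seq.size
    amd = a_md.tolist()
    add = a_dd.tolist()
    vM = np.full(M + 1, _NEG_INF)
    vI = np.full(M + 1, _NEG_INF)
    vD = np.full(M + 1, _NEG_INF)
    # backpointers: M: 0 entry, 1 from M, 2 from I, 3 from D; I: 1 M, 2 I; D: 1 M, 3 D
    bM = np.zeros((L + 1, M + 1), dtype=np.int8)
    bI = np.zeros((L + 1, M + 1), dtype=np.int8)
    bD = np.zeros((L + 1, M + 1), dtype=np.int8)

    best = _NEG_INF
    best_end: Optional[tuple[int, str, int]] = None  # (i, state, k)
    for i in range(1, L + 1):
        x = seq[i - 1]
        cand = np.empty((4, M))
        cand[0] = entry[1:]
        cand[1] = vM[:-1] + a_mm[:-1]
        cand[2] = vI[:-1] + a_im[:-1]
        cand[3] = vD[:-1] + a_dm[:-1]
        ptr = cand.argmax(axis=0)
        nM = np.full(M + 1, _NEG_INF)
        nM[1:] = msc[1:, x] + cand.max(axis=0)
        bM[i, 1:] = ptr

        from_m = vM + a_mi
        from_i = vI + a_ii
        use_m = from_m >= from_i
        nI = isc + np.where(use_m, from_m, from_i)
        nI[M] = _NEG_INF
        bI[i] = np.where(use_m, 1, 2)

        nm_list = nM.tolist()
        nd_list = [_NEG_INF] * (M + 1)
        d = _NEG_INF
        brow = bD[i]
        for k in range(2, M + 1):
            via_m = nm_list[k - 1] + amd[k - 1]
            via_d = d + add[k - 1]
            if via_m >= via_d:
                d = via_m
                brow[k] = 1
            else:
                d = via_d
                brow[k] = 3
            nd_list[k] = d
        nD = np.array(nd_list)
        vM, vI, vD = nM, nI, nD

        exits = vM[1:] + exit_m[1:]
        k_best = int(exits.argmax()) + 1
        if exits[k_best - 1] > best:
            best, best_end = float(exits[k_best - 1]), (i, "M", k_best)
        if vD[M] > best:
            best, best_end = float(vD[M]), (i, "D", M)
    if best_end is None:
        raise DataError("no viterbi path found")

    # traceback
    path: list[str] = []
    i, state, k = best_end
    end_res = i
    while True:
        path.append(f"{state}{k}")
        if state == "M":
            ptr = bM[i, k]
            if ptr == 0:
                i -= 1
                break
            i, k, state = i - 1, k - 1, {1: "M", 2: "I", 3: "D"}[int(ptr)]
        elif state == "I":
            ptr = bI[i, k]
            i, state = i - 1, ("M" if ptr == 1 else "I")
        else:  # D
            ptr = bD[i, k]
            k, state = k - 1, ("M" if ptr == 1 else "D")
    path.reverse()
    start_res = i  # number of flank residues before the first core emission
    return ViterbiResult(tuple(path), float(best / math.log(2)), (start_res, end_res))


@dataclass(frozen=True)
class HmmHit:
    """One scored sequence: forward bits plus the viterbi core interval."""

    seq_id: str
    bit_score: float
    start: int
    end: int
    passed: bool


def scan(
    profile: ProfileHmm,
    records: Sequence[ProteinRecord],
    threshold: float = DEFAULT_SCAN_THRESHOLD,
    min_len: int = DEFAULT_SCAN_MIN_LEN,
    mode: str = "local",
    compute_interval: bool = True,
) -> tuple[list[HmmHit], list[str]]:
    """Score a collection against the profile.

    Sequences of length at most ``min_len`` are skipped (returned in the
    second list), not scored as negatives — only sequences *longer* than
    ``min_len`` are used for the search.  Hits keep the input order.
    """
    hits: list[HmmHit] = []
    skipped: list[str] = []
    for rec in records:
        if len(rec.sequence) <= min_len:
            skipped.append(rec.id)
            continue
        bits = forward_bits(profile, rec, mode=mode)
        if compute_interval:
            vit = viterbi(profile, rec, mode=mode)
            start, end = vit.interval
        else:
            start, end = 0, len(rec.sequence)
        hits.append(HmmHit(rec.id, bits, start, end, bits >= threshold))
    return hits, skipped


def write_scan_report(path, hits: Sequence[HmmHit], skipped: Sequence[str], lengths: dict[str, int]) -> None:
    """TSV: id, length, bit_score, status(passed/failed/skipped)."""
    with open(path, "w") as fh:
        fh.write("id\tlength\tbit_score\tstatus\n")
        for hit in hits:
            status = "passed" if hit.passed else "failed"
            fh.write(f"{hit.seq_id}\t{lengths[hit.seq_id]}\t{hit.bit_score:.4f}\t{status}\n")
        for rid in skipped:
            fh.write(f"{rid}\t{lengths[rid]}\t\tskipped\n")


# ---------------------------------------------------------------------------
# plain-text serialization (HMMER3-like layout, own format)
# ---------------------------------------------------------------------------

_MAGIC = "GH51KIT-HMM 1"


def save_profile(path, profile: ProfileHmm) -> None:
    """Serialize to a documented plain-text format (probabilities, full precision)."""
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"M {profile.M}\n")
        fh.write(f"ALPH {AA20}\n")
        fh.write(f"ETA {profile.eta!r}\n")
        fh.write(f"TAU {profile.tau!r}\n")
        fh.write("BG " + " ".join(repr(float(v)) for v in profile.bg) + "\n")
        for k in range(1, profile.M + 1):
            fh.write(f"MATCH {k} " + " ".join(repr(float(v)) for v in profile.mat[k]) + "\n")
        for k in range(1, profile.M):
            vals = (
                profile.t_mm[k], profile.t_mi[k], profile.t_md[k],
                profile.t_im[k], profile.t_ii[k],
                profile.t_dm[k], profile.t_dd[k],
            )
            fh.write(f"TRANS {k} " + " ".join(repr(float(v)) for v in vals) + "\n")
        fh.write("//\n")


def load_profile(path) -> ProfileHmm:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _MAGIC:
        raise DataError(f"{path}: not a {_MAGIC} file")
    fields: dict[str, str] = {}
    match_lines: dict[int, list[float]] = {}
    trans_lines: dict[int, list[float]] = {}
    for ln in lines[1:]:
        if not ln or ln == "//":
            continue
        key, rest = ln.split(" ", 1)
        if key == "MATCH":
            k, vals = rest.split(" ", 1)
            match_lines[int(k)] = [float(v) for v in vals.split()]
        elif key == "TRANS":
            k, vals = rest.split(" ", 1)
            trans_lines[int(k)] = [float(v) for v in vals.split()]
        else:
            fields[key] = rest
    M = int(fields["M"])
    mat = np.zeros((M + 1, 20))
    for k in range(1, M + 1):
        mat[k] = match_lines[k]
    arrays = {name: np.zeros(M + 1) for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")}
    for k in range(1, M):
        vals = trans_lines[k]
        for name, v in zip(("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"), vals):
            arrays[name][k] = v
    return ProfileHmm(
        M=M,
        mat=mat,
        bg=np.array([float(v) for v in fields["BG"].split()]),
        eta=float(fields["ETA"]),
        tau=float(fields["TAU"]),
        **arrays,
    )
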