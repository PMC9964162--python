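"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the package
(path enumeration, window-by-window matching, exhaustive alignment
enumeration, path-length summation on a known tree) so agreement is
meaningful.
"""

from __future__ import annotations

import math
import random

from gh51kit.hmm import ProfileHmm
from gh51kit.io import AA20
from gh51kit.motifs import MotifPattern

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}


# ---------------------------------------------------------------------------
# motif scanning: every window, token by token
# ---------------------------------------------------------------------------

def brute_force_motif_starts(pattern: MotifPattern, seq: str) -> list[int]:
    starts = []
    L = len(pattern.tokens)
    for s in range(len(seq) - L + 1):
        ok = True
        for off, tok in enumerate(pattern.tokens):
            ch = seq[s + off]
            if tok is None:
                continue
            if ch not in tok:
                ok = False
                break
        if ok:
            starts.append(s)
    return starts


# ---------------------------------------------------------------------------
# profile HMM: exhaustive enumeration of every state path
# ---------------------------------------------------------------------------

def enumerate_hmm_scores(
    profile: ProfileHmm, seq: str, mode: str = "local"
) -> tuple[float, float]:
    """(forward bits, viterbi bits) by explicit enumeration of all paths.

    Mirrors the declared generative model: flank residues are free, core
    emissions score ``emission / background / eta``, local entry is
    uniform ``1/M`` over match states with exit probability ``tau`` from
    ``Mk`` (k < M) and 1 from ``M_M``/``D_M``; glocal enters at ``M1``
    and exits at ``M_M``/``D_M`` only.
    """
    M = profile.M
    eta = profile.eta
    tau = profile.tau
    x = [_AA_INDEX.get(ch, None) for ch in seq]
    L = len(x)
    weights: list[float] = []

    def emit(k: int, pos: int) -> float:
        xi = x[pos]
        if xi is None:  # X scores as background
            return 1.0 / eta
        return profile.mat[k][xi] / profile.bg[xi] / eta

    local = mode == "local"

    def cont(k: int) -> float:
        # probability mass left after the exit option at position k
        return (1.0 - tau) if (local and k < M) else 1.0

    def walk(state: str, k: int, pos: int, w: float) -> None:
        # `pos` is the next residue index to emit
        if state == "M":
            if pos >= L:
                return
            w *= emit(k, pos)
            pos += 1
            if k == M:
                weights.append(w)  # exit probability 1
                return
            if local:
                weights.append(w * tau)
            walk("M", k + 1, pos, w * cont(k) * profile.t_mm[k])
            walk("I", k, pos, w * cont(k) * profile.t_mi[k])
            walk("D", k + 1, pos, w * cont(k) * profile.t_md[k])
        elif state == "I":
            if pos >= L:
                return
            w *= 1.0 / eta  # insert emits background
            pos += 1
            walk("M", k + 1, pos, w * profile.t_im[k])
            walk("I", k, pos, w * profile.t_ii[k])
        else:  # D
            if k == M:
                weights.append(w)
                return
            walk("M", k + 1, pos, w * profile.t_dm[k])
            walk("D", k + 1, pos, w * profile.t_dd[k])

    entry_states = range(1, M + 1) if local else [1]
    entry_p = 1.0 / M if local else 1.0
    for k in entry_states:
        for start in range(L):
            walk("M", k, start, entry_p)

    if not weights:
        return (-math.inf, -math.inf)
    return (math.log2(math.fsum(weights)), math.log2(max(weights)))


# ---------------------------------------------------------------------------
# global affine-gap alignment: enumerate every alignment
# ---------------------------------------------------------------------------

def exhaustive_global_score(
    a: str, b: str, sub, gap_open: float, gap_extend: float
) -> float:
    """Best global alignment score over all alignments, by recursion.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``; no
    column may be gapped in both rows.  ``sub`` is a Biopython
    substitution matrix.
    """
    best = [-math.inf]

    def rec(i: int, j: int, score: float, prev: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub[a[i], b[j]], "m")
        if i < len(a):  # gap in b
            cost = gap_extend if prev == "gb" else gap_open
            rec(i + 1, j, score - cost, "gb")
        if j < len(b):  # gap in a
            cost = gap_extend if prev == "ga" else gap_open
            rec(i, j + 1, score - cost, "ga")

    rec(0, 0, 0.0, "")
    return best[0]


# ---------------------------------------------------------------------------
# additive distance matrices from random trees
# ---------------------------------------------------------------------------

def random_additive_case(rng: random.Random, n_taxa: int):
    """Random unrooted binary tree -> (taxa, matrix, bipartitions, total length).

    Distances are path sums on the tree, so the matrix is additive and
    neighbor joining must recover the topology and branch lengths.
    """
    taxa = [f"t{i}" for i in range(n_taxa)]
    # adjacency with branch lengths; start from a 3-star, attach leaves
    next_internal = [0]

    def new_internal() -> str:
        next_internal[0] += 1
        return f"n{next_internal[0]}"

    adj: dict[str, dict[str, float]] = {}

    def connect(u: str, v: str, w: float) -> None:
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def blen() -> float:
        return round(rng.uniform(0.05, 1.0), 3)

    center = new_internal()
    for t in taxa[:3]:
        connect(center, t, blen())
    edges = [(center, t) for t in taxa[:3]]
    for t in taxa[3:]:
        u, v = edges[rng.randrange(len(edges))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        mid = new_internal()
        w1 = round(w * rng.uniform(0.25, 0.75), 4)
        w2 = round(w - w1, 4)
        connect(u, mid, max(w1, 0.01))
        connect(mid, v, max(w2, 0.01))
        connect(mid, t, blen())
        edges.remove((u, v))
        edges.extend([(u, mid), (mid, v), (mid, t)])

    def path_length(src: str, dst: str) -> float:
        stack = [(src, None, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == dst:
                return dist
            for nbr, w in adj[node].items():
                if nbr != parent:
                    stack.append((nbr, node, dist + w))
        raise AssertionError("disconnected tree")

    import numpy as np

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            D[i, j] = D[j, i] = path_length(taxa[i], taxa[j])

    # bipartitions: for each internal edge, the leaf set on one side
    all_set = frozenset(taxa)
    ref = min(taxa)
    bips: set[frozenset[str]] = set()

    def side(u: str, v: str) -> frozenset[str]:
        # leaves reachable from v without crossing u
        out = set()
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if node.startswith("t"):
                out.add(node)
            for nbr in adj[node]:
                if nbr != parent:
                    stack.append((nbr, node))
        return frozenset(out)

    seen = set()
    for u in adj:
        for v in adj[u]:
            if (v, u) in seen or u.startswith("t") or v.startswith("t"):
                seen.add((u, v))
                continue
            seen.add((u, v))
            fs = side(u, v)
            if 2 <= len(fs) <= n_taxa - 2:
                bips.add(fs if ref not in fs else all_set - fs)

    total = sum(w for u in adj for w in adj[u].values()) / 2
    return taxa, D, bips, total
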