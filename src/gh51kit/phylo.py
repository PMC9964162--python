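"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap
support, and clade/catalysis congruence.

Neighbor joining with p-distances is a deliberate stand-in for
maximum-likelihood tree search; congruence conclusions drawn from it are
qualitative.  Bootstrap support is classical column resampling: the
percentage of replicate NJ trees containing each internal bipartition of
the reference tree.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DataError
from .io import GAP, Msa
from .motifs import CatalyticCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric distance matrix over named taxa, zero diagonal."""

    taxa: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise DataError("matrix shape must match taxon count")
        if len(set(self.taxa)) != n:
            raise DataError("taxa must be unique")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise DataError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal must be zero")
        if np.any(self.matrix < -1e-12):
            raise DataError("distances must be non-negative")


def p_distance_matrix(msa: Msa, zero_overlap: str = "error") -> DistanceMatrix:
    """Pairwise p-distances: mismatches over columns where both rows
    have residues.

    ``zero_overlap`` controls pairs with no comparable columns:
    ``"error"`` raises, ``"max"`` assigns distance 1.0 (useful inside
    bootstrap replicates).
    """
    if msa.n_rows < 3:
        raise DataError("p-distance matrix needs at least 3 rows")
    codes = np.zeros((msa.n_rows, msa.n_cols), dtype=np.uint8)
    for i, (_, s) in enumerate(msa.rows):
        codes[i] = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    gap_code = ord(GAP)
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (codes[i] != gap_code) & (codes[j] != gap_code)
            comparable = int(both.sum())
            if comparable == 0:
                if zero_overlap == "max":
                    d[i, j] = d[j, i] = 1.0
                    continue
                raise DataError(
                    f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            mism = int(((codes[i] != codes[j]) & both).sum())
            d[i, j] = d[j, i] = mism / comparable
    return DistanceMatrix(tuple(msa.ids), d)


@dataclass
class TreeNode:
    """Rooted-orientation tree node; ``support`` belongs to the edge above."""

    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """A tree with branch lengths; unrooted trees use a trifurcating root."""

    root: TreeNode

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.name or "")
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode, length: Optional[float]) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                sup = ""
                if with_support and node.support is not None:
                    sup = f"{node.support:g}"
                label = f"({inner}){sup}"
            return label if length is None else f"{label}:{length:.6g}"

        return fmt(self.root, None) + ";"

    def leafset(self, node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name or ""])
        out: set[str] = set()
        for child, _ in node.children:
            out |= self.leafset(child)
        return frozenset(out)

    def bipartitions(self) -> set[frozenset[str]]:
        """Canonical nontrivial bipartitions (one per internal edge).

        Each bipartition is represented by the side *not* containing the
        lexicographically smallest leaf.
        """
        all_leaves = frozenset(self.leaves())
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name or ""])
            below: set[str] = set()
            for child, _ in node.children:
                below |= walk(child)
            fs = frozenset(below)
            if node is not self.root and 2 <= len(fs) <= len(all_leaves) - 2:
                out.add(fs if ref not in fs else all_leaves - fs)
            return fs

        walk(self.root)
        return out


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Deterministic: ties in the Q criterion are broken by the
    lexicographically smallest (cluster, cluster) label pair, where a
    cluster is labelled by its smallest leaf name.  Negative branch
    length estimates are clamped to zero with a warning.
    """
    n = len(dm.taxa)
    if n < 3:
        raise DataError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    labels: list[str] = list(dm.taxa)  # tie-break key per active cluster
    D = dm.matrix.astype(float).copy()

    def clamp(x: float, what: str) -> float:
        if x < 0:
            if x < -1e-9:
                logger.warning("negative NJ branch length %.3g clamped to 0 (%s)", x, what)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = [
            (i, j)
            for i in range(m)
            for j in range(i + 1, m)
            if Q[i, j] <= qmin + 1e-12
        ]
        i, j = min(candidates, key=lambda p: tuple(sorted((labels[p[0]], labels[p[1]]))))
        dij = D[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, labels[i]), clamp(lj, labels[j])
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_d = (D[i] + D[j] - dij) / 2
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.zeros((m - 1, m - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = D_new[:-1, -1] = new_d[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]
        D = D_new

    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = clamp((dab + dac - dbc) / 2, labels[0])
    lb = clamp((dab + dbc - dac) / 2, labels[1])
    lc = clamp((dac + dbc - dab) / 2, labels[2])
    root = TreeNode(children=[(a, la), (b, lb), (c, lc)])
    return Tree(root)


def bootstrap_support(msa: Msa, n_reps: int, seed: int) -> Tree:
    """Reference NJ tree with column-resampling bootstrap supports (0-100)."""
    if n_reps < 1:
        raise DataError("n_reps must be at least 1")
    reference = nj_tree(p_distance_matrix(msa))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in reference.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
        rep_msa = msa.take_columns([int(c) for c in cols])
        rep_tree = nj_tree(p_distance_matrix(rep_msa, zero_overlap="max"))
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(reference.leaves())
    ref_leaf = min(all_leaves)

    def annotate(tree: Tree, node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name or ""])
        below: set[str] = set()
        for child, _ in node.children:
            below |= annotate(tree, child)
        fs = frozenset(below)
        if node is not tree.root and 2 <= len(fs) <= len(all_leaves) - 2:
            key = fs if ref_leaf not in fs else all_leaves - fs
            node.support = 100.0 * counts[key] / n_reps
        return fs

    annotate(reference, reference.root)
    return reference


def reroot(tree: Tree, outgroup_taxon: str) -> Tree:
    """Root the tree on the pendant edge of ``outgroup_taxon``.

    The new root bisects that edge; the outgroup leaf becomes one child
    and the rest of the tree the other.  Edge supports follow their
    edges.
    """
    # undirected adjacency with (length, support) per edge
    adj: dict[int, list[tuple[int, float, Optional[float]]]] = {}
    nodes: dict[int, TreeNode] = {}

    def register(node: TreeNode) -> int:
        nid = id(node)
        nodes[nid] = node
        adj.setdefault(nid, [])
        return nid

    def build(node: TreeNode) -> None:
        nid = register(node)
        for child, length in node.children:
            cid = register(child)
            adj[nid].append((cid, length, child.support))
            adj[cid].append((nid, length, child.support))
            build(child)

    build(tree.root)
    target = next(
        (nid for nid, nd in nodes.items() if nd.is_leaf and nd.name == outgroup_taxon),
        None,
    )
    if target is None:
        raise DataError(f"outgroup taxon {outgroup_taxon!r} not in tree")
    (nbr, length, support) = adj[target][0]

    def orient(nid: int, parent: Optional[int]) -> TreeNode:
        src = nodes[nid]
        new = TreeNode(name=src.name)
        for cid, clen, csup in adj[nid]:
            if cid == parent:
                continue
            child = orient(cid, nid)
            child.support = csup
            new.children.append((child, clen))
        return new

    out_leaf = TreeNode(name=outgroup_taxon)
    rest = orient(nbr, target)
    rest.support = support
    root = TreeNode(children=[(out_leaf, length / 2), (rest, length / 2)])
    return Tree(root)


def collapse_low_support(tree: Tree, cutoff: float = 90.0) -> Tree:
    """Collapse internal edges whose support is below ``cutoff``."""

    def walk(node: TreeNode) -> TreeNode:
        new = TreeNode(name=node.name, support=node.support)
        for child, length in node.children:
            rebuilt = walk(child)
            if (
                not rebuilt.is_leaf
                and rebuilt.support is not None
                and rebuilt.support < cutoff
            ):
                for gchild, glen in rebuilt.children:
                    new.children.append((gchild, glen + length))
            else:
                new.children.append((rebuilt, length))
        return new

    return Tree(walk(tree.root))


def mrca(tree: Tree, taxa: set[str]) -> TreeNode:
    """Smallest clade of a rooted tree containing all ``taxa``."""
    if not taxa:
        raise DataError("empty taxon set")
    missing = taxa - set(tree.leaves())
    if missing:
        raise DataError(f"taxa not in tree: {sorted(missing)}")
    best: Optional[TreeNode] = None
    best_size = np.inf

    def walk(node: TreeNode) -> frozenset[str]:
        nonlocal best, best_size
        fs = (
            frozenset([node.name or ""])
            if node.is_leaf
            else frozenset().union(*(walk(c) for c, _ in node.children))
        )
        if taxa <= fs and len(fs) < best_size:
            best, best_size = node, len(fs)
        return fs

    walk(tree.root)
    assert best is not None
    return best


def clade_catalysis_congruence(
    tree: Tree,
    calls: Sequence[CatalyticCall],
    clade_seed_taxa: set[str],
    outgroup: Sequence[str],
) -> dict:
    """Compare clade membership with catalytic status.

    The tree is rooted on the first outgroup taxon's pendant edge; the
    clade is the smallest rooted clade containing all seed taxa.  Returns
    per-status counts and fractions inside and outside the clade
    (outgroup taxa excluded from "outside"), plus the exceptions: inside
    members deviating from the modal inside status, and outside members
    carrying it.
    """
    if not clade_seed_taxa:
        raise DataError("empty clade seed set")
    if not outgroup:
        raise DataError("an explicit outgroup is required")
    rooted = reroot(tree, outgroup[0])
    clade_node = mrca(rooted, set(clade_seed_taxa))
    inside = set(rooted.leafset(clade_node))
    outside = set(rooted.leaves()) - inside - set(outgroup)

    status = {c.seq_id: str(c.status) for c in calls}

    def summarize(members: set[str]) -> dict:
        counts: dict[str, int] = {}
        for m in sorted(members):
            counts[status.get(m, "unknown")] = counts.get(status.get(m, "unknown"), 0) + 1
        total = len(members)
        return {
            "n": total,
            "counts": counts,
            "fractions": {k: v / total for k, v in counts.items()} if total else {},
        }

    inside_summary = summarize(inside)
    modal = max(inside_summary["counts"], key=lambda k: (inside_summary["counts"][k], k)) if inside else None
    return {
        "clade_members": sorted(inside),
        "inside": inside_summary,
        "outside": summarize(outside),
        "modal_inside_status": modal,
        "exceptions": {
            "inside_deviating": sorted(
                m for m in inside if status.get(m, "unknown") != modal
            ),
            "outside_with_modal_status": sorted(
                m for m in outside if status.get(m, "unknown") == modal
            ),
        },
    }


def write_congruence_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
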