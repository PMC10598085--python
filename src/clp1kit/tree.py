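"""Distance-based phylogenetics: NJ trees, bootstrap support, midpoint root.

Trees are `skbio.TreeNode` objects with branch lengths on ``length`` and
bipartition support (0-100) on a ``support`` attribute of internal nodes.
Neighbor joining is implemented directly (with the conventional clamping of
negative branch lengths to zero, moving the deficit to the sibling edge) so
that exactly additive distances reproduce their generating tree; supports
come from a nonparametric column-resampling bootstrap.
"""

from __future__ import annotations

import io
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .msa import GAP, MultipleAlignment


def p_distance_matrix(aln: MultipleAlignment) -> np.ndarray:
    """Pairwise fraction-difference over columns where both rows have residues."""
    n = len(aln.rows)
    arr = np.array([list(r) for r in aln.rows])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arr[i] != GAP) & (arr[j] != GAP)
            m = int(both.sum())
            diff = int((arr[i][both] != arr[j][both]).sum()) if m else 0
            d[i, j] = d[j, i] = diff / m if m else 1.0
    return d


def kimura_correct(p: np.ndarray) -> np.ndarray:
    """Kimura's (1983) protein-distance correction d = -ln(1 - p - 0.2 p^2).

    Saturated fractions (argument <= 0) are capped at 10 substitutions/site.
    """
    arg = 1.0 - p - 0.2 * p * p
    out = np.where(arg > 0, -np.log(np.clip(arg, 1e-300, None)), 10.0)
    np.fill_diagonal(out, 0.0)
    return np.minimum(out, 10.0)


def alignment_distances(aln: MultipleAlignment, kimura: bool = True) -> np.ndarray:
    d = p_distance_matrix(aln)
    return kimura_correct(d) if kimura else d


def nj_tree(dist: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Returned as a `TreeNode` with a trifurcating root (the standard
    representation of an unrooted tree).  Negative NJ branch-length
    estimates are clamped to 0 and the deficit moved to the sibling edge.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if len(labels) != n:
        raise ValueError("labels/matrix size mismatch")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    D = dist.copy()
    idx = list(range(n))

    while len(idx) > 3:
        k = len(idx)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        a, b = np.unravel_index(np.argmin(Q), Q.shape)
        if a > b:
            a, b = b, a
        dij = sub[a, b]
        la = 0.5 * dij + (r[a] - r[b]) / (2.0 * (k - 2))
        lb = dij - la
        if la < 0:
            lb += -la
            la = 0.0
        if lb < 0:
            la += -lb
            lb = 0.0
        ia, ib = idx[a], idx[b]
        child_a, child_b = nodes[ia], nodes[ib]
        child_a.length = la
        child_b.length = lb
        parent = TreeNode(children=[child_a, child_b])
        # distances from the new node to the remaining ones
        new_row = np.zeros(D.shape[0] + 1)
        for pos, other in enumerate(idx):
            if other in (ia, ib):
                continue
            new_row[other] = 0.5 * (D[ia, other] + D[ib, other] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        idx = [i for i in idx if i not in (ia, ib)] + [D.shape[0] - 1]

    # final three-way join (closed form)
    i, j, k = idx
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = ln
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    root.length = None
    return root


def tree_from_alignment(aln: MultipleAlignment, kimura: bool = True) -> TreeNode:
    return nj_tree(alignment_distances(aln, kimura=kimura), list(aln.ids))


# ---------------------------------------------------------------------------
# bipartitions and bootstrap

def _bipartitions(tree: TreeNode) -> dict[frozenset[str], TreeNode]:
    """Map each internal edge to its tip-side bipartition (canonicalised)."""
    all_tips = frozenset(t.name for t in tree.tips())
    out: dict[frozenset[str], TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out[key] = node
    return out


def bootstrap_support(
    aln: MultipleAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    kimura: bool = True,
) -> TreeNode:
    """NJ tree with column-resampling bootstrap supports on internal edges."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = tree_from_alignment(aln, kimura=kimura)
    parts = _bipartitions(tree)
    counts = {key: 0 for key in parts}
    rng = np.random.default_rng(seed)
    ncol = aln.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rows = tuple("".join(r[c] for c in cols) for r in aln.rows)
        rep = MultipleAlignment(aln.ids, rows)
        rep_tree = tree_from_alignment(rep, kimura=kimura)
        rep_parts = set(_bipartitions(rep_tree))
        for key in counts:
            if key in rep_parts:
                counts[key] += 1
    for key, node in parts.items():
        node.support = 100.0 * counts[key] / n_reps
    return tree


# ---------------------------------------------------------------------------
# rooting and newick I/O

def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("need at least two leaves to midpoint-root")
    rooted = tree.copy().root_at_midpoint(reset=True)
    depths = sorted((rooted.distance(t) for t in rooted.tips()), reverse=True)
    if depths[0] <= 0:
        raise ValueError("zero-length longest path; midpoint undefined")
    return rooted


def max_root_imbalance(rooted: TreeNode) -> float:
    """|d1 - d2| of the two deepest root-to-leaf distances (0 when balanced)."""
    children = rooted.children
    side_max = []
    for ch in children:
        base = ch.length or 0.0
        tips = list(ch.tips()) or [ch]
        side_max.append(max(base + (ch.distance(t) if t is not ch else 0.0)
                            for t in tips))
    side_max.sort(reverse=True)
    return abs(side_max[0] - side_max[1])


def _fmt_len(x: float | None) -> str:
    if x is None:
        return ""
    return f":{float(f'{x:.6g}'):g}"


def _newick(node: TreeNode, with_support: bool) -> str:
    if node.is_tip():
        return f"{node.name}{_fmt_len(node.length)}"
    inner = ",".join(_newick(c, with_support) for c in node.children)
    label = ""
    if with_support and getattr(node, "support", None) is not None:
        label = f"{node.support:g}"
    elif node.name:
        label = node.name
    return f"({inner}){label}{_fmt_len(node.length)}"


def write_newick(tree: TreeNode, path: str | Path, with_support: bool = True) -> None:
    Path(path).write_text(_newick(tree, with_support) + ";\n")


def newick_string(tree: TreeNode, with_support: bool = True) -> str:
    return _newick(tree, with_support) + ";"


def read_newick(source: str | Path) -> TreeNode:
    """Read a newick tree; numeric internal-node labels become supports."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and not source.rstrip().endswith(";")):
        tree = TreeNode.read(str(source), convert_underscores=False)
    else:
        tree = TreeNode.read(io.StringIO(str(source)), convert_underscores=False)
    for node in tree.non_tips(include_self=True):
        if node.name:
            try:
                node.support = float(node.name)
                node.name = None
            except ValueError:
                pass
    return tree
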