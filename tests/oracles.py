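"""Independent reference implementations used only by the test suite.

These are deliberately separate routes from the package code: a plain
dynamic-programming Smith-Waterman / Needleman-Wunsch scorer written
directly from the recurrences, a random additive-tree generator with its
path-length metric, and a brute-force physicochemical property
intersection.  They exist to cross-check the package, never to power it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from clp1kit.scoring import AA_INDEX, ScoringScheme

NEG = -1e18


@njit(cache=True)
def _sw_score(a, b, sub, gap_open_total, gap_ext):  # pragma: no cover
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open_total, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - gap_open_total, F[i - 1, j] - gap_ext)
            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
            if H[i, j] > best:
                best = H[i, j]
    return best


@njit(cache=True)
def _nw_score(a, b, sub, gap_open_total, gap_ext):  # pragma: no cover
    """Global score with free terminal gaps (semi-global)."""
    n, m = len(a), len(b)
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    # free leading gaps: H holds the best score in any state
    for j in range(m + 1):
        H[0, j] = 0.0
    for i in range(n + 1):
        H[i, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open_total, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - gap_open_total, F[i - 1, j] - gap_ext)
            H[i, j] = max(H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]],
                          E[i, j], F[i, j])
    # free trailing gaps
    best = max(H[n, m], E[n, m], F[n, m])
    for i in range(n + 1):
        if H[i, m] > best:
            best = H[i, m]
    for j in range(m + 1):
        if H[n, j] > best:
            best = H[n, j]
    return best


def _encode(seq: str) -> np.ndarray:
    return np.array([AA_INDEX[c] for c in seq], dtype=np.int64)


def smith_waterman_score(a: str, b: str, scheme: ScoringScheme | None = None) -> int:
    """Exhaustive local-alignment score under the BLAST gap convention."""
    scheme = scheme or ScoringScheme()
    return int(_sw_score(_encode(a), _encode(b), scheme.matrix.astype(np.float64),
                         float(scheme.gap_open + scheme.gap_extend),
                         float(scheme.gap_extend)))


def needleman_wunsch_score(a: str, b: str, scheme: ScoringScheme | None = None) -> int:
    """Exhaustive global (free-end-gap) score under the same convention."""
    scheme = scheme or ScoringScheme()
    return int(_nw_score(_encode(a), _encode(b), scheme.matrix.astype(np.float64),
                         float(scheme.gap_open + scheme.gap_extend),
                         float(scheme.gap_extend)))


def random_protein(rng: np.random.Generator, length: int) -> str:
    from clp1kit.scoring import AA_ORDER
    return "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=length))


# ---------------------------------------------------------------------------
# random additive trees

def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree topology with positive branch lengths.

    Returns (labels, D) where D is the exact leaf-to-leaf path-length matrix.
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    # start from a star of 3, repeatedly attach leaves to random edges
    # represent as adjacency with lengths on an undirected graph
    import itertools
    next_id = [n_leaves]
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n_leaves)}

    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def new_node():
        k = next_id[0]
        next_id[0] += 1
        adj.setdefault(k, {})
        return k

    def blen():
        return float(rng.uniform(0.05, 1.0))

    center = new_node()
    for leaf in range(3):
        add_edge(center, leaf, blen())
    for leaf in range(3, n_leaves):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(0, len(edges))]
        w = adj[u][v]
        del adj[u][v]
        del adj[v][u]
        mid = new_node()
        cut = float(rng.uniform(0.25, 0.75)) * w
        add_edge(u, mid, cut)
        add_edge(mid, v, w - cut)
        add_edge(mid, leaf, blen())

    # all-pairs leaf distances by BFS over the tree
    D = np.zeros((n_leaves, n_leaves))
    for s in range(n_leaves):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for t in range(n_leaves):
            D[s, t] = dist[t]
    D = (D + D.T) / 2.0  # guard against float path-order asymmetry
    return labels, D


def tree_distance_matrix(tree, labels):
    """Leaf-to-leaf path lengths of an skbio TreeNode, ordered by labels."""
    tips = {t.name: t for t in tree.tips()}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tips[labels[i]].distance(tips[labels[j]])
            D[i, j] = D[j, i] = d
    return D


def property_intersection_rank(residues: str) -> int:
    """Brute-force count of physicochemical properties uniformly present or
    uniformly absent across the residues."""
    from clp1kit.msa import PROPERTY_SETS
    count = 0
    for members in PROPERTY_SETS.values():
        flags = [r in members for r in residues]
        if all(flags) or not any(flags):
            count += 1
    return count
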