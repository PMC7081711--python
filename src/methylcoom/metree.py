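"""Balanced minimum-evolution trees from distance matrices.

Implements the distance-based tree construction used to order reference
subpopulations along a differentiation axis: a neighbor-joining start
topology, balanced nearest-neighbor-interchange (NNI) rearrangements that
greedily reduce the balanced tree length (Pauplin's formula,
``sum_{i<j} 2^(1-p_ij) d_ij`` with ``p_ij`` the topological leaf-leaf path
length), and balanced branch-length estimation with midpoint-weighted
subtree averages (Desper & Gascuel's scheme).  Branch lengths are clamped
at zero.  Everything is deterministic: NJ ties and NNI acceptance follow a
fixed node-id ordering with first-improvement moves.

Trees here are small (a handful of subpopulations plus tumor samples), so
all routines favor clarity over asymptotic tricks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["MeTree", "build_me_tree"]

_EPS = 1e-12


@dataclass
class MeTree:
    """Unrooted tree with branch lengths; leaves carry string labels."""

    adj: dict[int, dict[int, float]]
    labels: dict[int, str]  # leaf node id -> label

    def __post_init__(self) -> None:
        self._by_label = {v: k for k, v in self.labels.items()}

    # -- basic queries ------------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self._by_label)

    def leaf_node(self, label: str) -> int:
        return self._by_label[label]

    def degree(self, node: int) -> int:
        return len(self.adj[node])

    def total_length(self) -> float:
        return sum(l for nbrs in self.adj.values() for l in nbrs.values()) / 2.0

    def path(self, a: str, b: str) -> list[int]:
        """Node ids along the unique path between two leaves (inclusive)."""
        start, goal = self._by_label[a], self._by_label[b]
        prev: dict[int, int] = {start: start}
        stack = [start]
        while stack:
            u = stack.pop()
            if u == goal:
                break
            for v in self.adj[u]:
                if v not in prev:
                    prev[v] = u
                    stack.append(v)
        nodes = [goal]
        while nodes[-1] != start:
            nodes.append(prev[nodes[-1]])
        return nodes[::-1]

    def path_length(self, nodes: Sequence[int]) -> float:
        return float(sum(self.adj[u][v] for u, v in zip(nodes[:-1], nodes[1:])))

    def distance(self, a: str, b: str) -> float:
        return self.path_length(self.path(a, b))

    def distance_matrix(self, labels: Sequence[str]) -> np.ndarray:
        n = len(labels)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = self.distance(labels[i], labels[j])
        return out

    # -- newick -------------------------------------------------------------

    def to_newick(self) -> str:
        if len(self.labels) == 1:
            (node,) = self.labels
            return f"{self.labels[node]};"
        if len(self.labels) == 2:
            (a, b) = sorted(self.labels)
            return f"({self.labels[a]}:{self.adj[a][b]:g},{self.labels[b]}:0);"
        root = min(n for n in self.adj if n not in self.labels)

        def fmt(node: int, parent: int) -> str:
            children = sorted(v for v in self.adj[node] if v != parent)
            if not children:
                return f"{self.labels[node]}:{self.adj[node][parent]:g}"
            inner = ",".join(fmt(c, node) for c in children)
            if parent == node:  # root
                return f"({inner})"
            return f"({inner}):{self.adj[node][parent]:g}"

        return fmt(root, root) + ";"


# ---------------------------------------------------------------------------
# construction


def _validate_distances(dist: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError(f"distance matrix shape {dist.shape} does not match {n} labels")
    if len(set(labels)) != n:
        raise ValueError("duplicate taxon labels")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix has non-zero diagonal")
    if np.any(dist < 0):
        raise ValueError("negative distances")
    return dist


def _nj_topology(dist: np.ndarray) -> tuple[dict[int, set[int]], int]:
    """Neighbor-joining topology; returns (adjacency, next free node id).

    Leaves are node ids 0..n-1 (matrix order).  Branch lengths are not kept:
    the balanced estimator recomputes them on the final topology.
    """
    n = dist.shape[0]
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    active = list(range(n))
    d = {(i, j): dist[i, j] for i in range(n) for j in range(n)}
    nxt = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        u = nxt
        nxt += 1
        adj[u] = {i, j}
        adj[i].add(u)
        adj[j].add(u)
        active = [k for k in active if k not in (i, j)] + [u]
        for k in active:
            if k == u:
                continue
            val = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[u, k] = d[k, u] = val
        d[u, u] = 0.0
    if len(active) == 3:
        u = nxt
        nxt += 1
        adj[u] = set(active)
        for k in active:
            adj[k].add(u)
    else:  # exactly 2 active nodes
        a, b = active
        adj[a].add(b)
        adj[b].add(a)
    return adj, nxt


def _leaf_topo_distances(adj: dict[int, set[int]], leaves: Sequence[int]) -> np.ndarray:
    """Topological (edge-count) distances between leaves via BFS."""
    idx = {leaf: k for k, leaf in enumerate(leaves)}
    n = len(leaves)
    out = np.zeros((n, n), dtype=int)
    for leaf in leaves:
        depth = {leaf: 0}
        frontier = [leaf]
        while frontier:
            new = []
            for u in frontier:
                for v in adj[u]:
                    if v not in depth:
                        depth[v] = depth[u] + 1
                        new.append(v)
            frontier = new
        for other, k in idx.items():
            out[idx[leaf], k] = depth[other]
    return out


def _balanced_length(adj: dict[int, set[int]], dist: np.ndarray, leaves: Sequence[int]) -> float:
    """Pauplin's balanced tree length for a topology."""
    p = _leaf_topo_distances(adj, leaves)
    n = len(leaves)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += dist[leaves[i], leaves[j]] * 2.0 ** (1 - p[i, j])
    return total


def _bnni(adj: dict[int, set[int]], dist: np.ndarray, leaves: Sequence[int]) -> None:
    """Balanced NNI: first-improvement sweeps over internal edges, in place."""
    current = _balanced_length(adj, dist, leaves)
    leafset = set(leaves)
    improved = True
    while improved:
        improved = False
        internal_edges = sorted(
            (u, v)
            for u in adj
            for v in adj[u]
            if u < v and u not in leafset and v not in leafset
        )
        for u, v in internal_edges:
            a, b = sorted(adj[u] - {v})
            c, d = sorted(adj[v] - {u})
            # the two alternative quartet arrangements around edge (u, v)
            for x, y in ((b, c), (b, d)):
                adj[u].remove(x); adj[x].remove(u)
                adj[v].remove(y); adj[y].remove(v)
                adj[u].add(y); adj[y].add(u)
                adj[v].add(x); adj[x].add(v)
                cand = _balanced_length(adj, dist, leaves)
                if cand < current - _EPS * max(1.0, abs(current)):
                    current = cand
                    improved = True
                    break
                # undo
                adj[u].remove(y); adj[y].remove(u)
                adj[v].remove(x); adj[x].remove(v)
                adj[u].add(x); adj[x].add(u)
                adj[v].add(y); adj[y].add(v)
            if improved:
                break


def _subtree_weights(
    adj: dict[int, set[int]], root: int, banned: int, leafset: set[int], n_leaves: int
) -> np.ndarray:
    """Balanced leaf weights of the subtree at ``root`` away from ``banned``.

    Each leaf's weight halves at every internal branching passed, so sibling
    subtrees contribute equally regardless of size.
    """
    w = np.zeros(n_leaves)

    def rec(node: int, parent: int, weight: float) -> None:
        if node in leafset:
            w[node] = weight
            return
        children = [x for x in adj[node] if x != parent]
        share = weight / len(children)
        for c in children:
            rec(c, node, share)

    rec(root, banned, 1.0)
    return w


def _balanced_branch_lengths(
    adj: dict[int, set[int]], dist: np.ndarray, leaves: Sequence[int]
) -> dict[int, dict[int, float]]:
    leafset = set(leaves)
    n = dist.shape[0]

    def avg(wa: np.ndarray, wb: np.ndarray) -> float:
        return float(wa @ dist @ wb)

    out: dict[int, dict[int, float]] = {u: {} for u in adj}
    for u in adj:
        for v in adj[u]:
            if u > v:
                continue
            if u in leafset and v in leafset:  # two-taxon tree
                length = dist[u, v]
            elif u in leafset or v in leafset:
                leaf, inner = (u, v) if u in leafset else (v, u)
                x, y = sorted(adj[inner] - {leaf})
                wi = np.zeros(n)
                wi[leaf] = 1.0
                wx = _subtree_weights(adj, x, inner, leafset, n)
                wy = _subtree_weights(adj, y, inner, leafset, n)
                length = 0.5 * (avg(wi, wx) + avg(wi, wy) - avg(wx, wy))
            else:
                a, b = sorted(adj[u] - {v})
                c, d = sorted(adj[v] - {u})
                wa = _subtree_weights(adj, a, u, leafset, n)
                wb = _subtree_weights(adj, b, u, leafset, n)
                wc = _subtree_weights(adj, c, v, leafset, n)
                wd = _subtree_weights(adj, d, v, leafset, n)
                length = 0.5 * (
                    0.5 * (avg(wa, wc) + avg(wb, wd) + avg(wa, wd) + avg(wb, wc))
                    - avg(wa, wb)
                    - avg(wc, wd)
                )
            length = max(0.0, length)
            out[u][v] = length
            out[v][u] = length
    return out


def build_me_tree(dist: np.ndarray, labels: Sequence[str]) -> MeTree:
    """Build a balanced minimum-evolution tree from a distance matrix.

    NJ start tree, balanced-NNI rearrangements, balanced branch lengths
    (clamped at >= 0).  Two taxa yield a single edge of length ``d(1,2)``;
    fewer than two taxa are rejected.
    """
    labels = list(labels)
    dist = _validate_distances(dist, labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    leaves = list(range(n))
    if n == 2:
        adj_topo: dict[int, set[int]] = {0: {1}, 1: {0}}
    else:
        adj_topo, _ = _nj_topology(dist)
        if n >= 4:
            _bnni(adj_topo, dist, leaves)
    lengths = _balanced_branch_lengths(adj_topo, dist, leaves)
    return MeTree(adj=lengths, labels={i: labels[i] for i in range(n)})
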