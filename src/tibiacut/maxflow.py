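"""Minimum s-t cut solvers for two-terminal pixel graphs.

Two interchangeable backends compute the same cut:

* :class:`DinicSolver` — a self-contained augmenting-path (Dinic) solver
  with exact floating-point capacities.  It is the reference backend used
  by the enumeration oracle tests; it is pure Python and intended for
  small graphs.
* :func:`scipy_min_cut` — a fast backend on top of
  ``scipy.sparse.csgraph.maximum_flow``.  scipy requires integer
  capacities, so float capacities are scaled and rounded; the scale is
  chosen as large as possible (up to ``2**20``) while keeping the total
  capacity below 2^31, because scipy's solver overflows silently beyond
  int32 range.  For the smooth energies produced here the induced cut is
  identical in practice and the cut values agree to the quantisation step.

Both return the *source side* of a minimum cut (the set of nodes reachable
from the source in the residual network), which downstream code interprets
as the foreground.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

__all__ = ["DinicSolver", "scipy_min_cut", "QUANT_SCALE"]

QUANT_SCALE = 1 << 20  # capacity quantisation step for the scipy backend


class DinicSolver:
    """Dinic max-flow on an explicit arc list with float capacities.

    Arcs are stored pairwise: arc ``2k`` and its reverse ``2k + 1``.
    ``add_edge(u, v, cap, rev_cap)`` creates both directions at once, so an
    undirected n-link is a single call with ``cap == rev_cap``.
    """

    def __init__(self, n_nodes: int) -> None:
        self.n = n_nodes
        self.head: list[list[int]] = [[] for _ in range(n_nodes)]
        self.to: list[int] = []
        self.cap: list[float] = []

    def add_edge(self, u: int, v: int, cap: float, rev_cap: float = 0.0) -> None:
        if cap < 0 or rev_cap < 0:
            raise ValueError("capacities must be non-negative")
        self.head[u].append(len(self.to))
        self.to.append(v)
        self.cap.append(float(cap))
        self.head[v].append(len(self.to))
        self.to.append(u)
        self.cap.append(float(rev_cap))

    def _bfs_levels(self, s: int, t: int) -> list[int] | None:
        level = [-1] * self.n
        level[s] = 0
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for e in self.head[u]:
                v = self.to[e]
                if level[v] < 0 and self.cap[e] > 1e-12:
                    level[v] = level[u] + 1
                    queue.append(v)
        return level if level[t] >= 0 else None

    def _dfs_push(self, u: int, t: int, f: float, level: list[int], it: list[int]) -> float:
        if u == t:
            return f
        while it[u] < len(self.head[u]):
            e = self.head[u][it[u]]
            v = self.to[e]
            if self.cap[e] > 1e-12 and level[v] == level[u] + 1:
                pushed = self._dfs_push(v, t, min(f, self.cap[e]), level, it)
                if pushed > 0:
                    self.cap[e] -= pushed
                    self.cap[e ^ 1] += pushed
                    return pushed
            it[u] += 1
        return 0.0

    def max_flow(self, s: int, t: int) -> float:
        flow = 0.0
        while True:
            level = self._bfs_levels(s, t)
            if level is None:
                return flow
            it = [0] * self.n
            while True:
                pushed = self._dfs_push(s, t, float("inf"), level, it)
                if pushed <= 0:
                    break
                flow += pushed

    def source_side(self, s: int) -> np.ndarray:
        """Nodes reachable from ``s`` in the residual graph (call after
        :meth:`max_flow`)."""
        seen = np.zeros(self.n, dtype=bool)
        seen[s] = True
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for e in self.head[u]:
                v = self.to[e]
                if not seen[v] and self.cap[e] > 1e-12:
                    seen[v] = True
                    queue.append(v)
        return seen


def scipy_min_cut(
    n_nodes: int,
    rows: np.ndarray,
    cols: np.ndarray,
    caps: np.ndarray,
    source: int,
    sink: int,
) -> tuple[float, np.ndarray]:
    """Min cut via scipy's max-flow on a quantised directed capacity matrix.

    Parameters give the directed arcs ``rows[k] -> cols[k]`` with float
    capacity ``caps[k]`` (parallel arcs are summed).  Returns the cut value
    (de-quantised) and the boolean source-side membership per node.
    """
    caps = np.asarray(caps, dtype=np.float64)
    # scipy's max-flow overflows silently once capacities (or the flow
    # value) leave int32 range; bound the total quantised capacity by 2^31
    scale = float(max(1, min(QUANT_SCALE, int((2**31 - 1) // max(caps.sum(), 1.0)))))
    q = np.rint(caps * scale).astype(np.int64)
    graph = csr_matrix((q, (rows, cols)), shape=(n_nodes, n_nodes))
    graph.sum_duplicates()
    graph.eliminate_zeros()
    result = maximum_flow(graph, source, sink)
    residual = graph - result.flow  # reverse arcs get residual = +flow
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual > 0, source, directed=True,
                                    return_predecessors=False)
    side = np.zeros(n_nodes, dtype=bool)
    side[reachable] = True
    return result.flow_value / scale, side
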