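"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own recursions: ancestral states come
from the closed-form GLS projection under the Brownian covariance matrix, and
the major-axis slope from a golden-section search over line angles minimizing
total perpendicular squared distance.
"""

from __future__ import annotations

import math

import numpy as np

from stingless_ssd.phylo_io import PhyloTree


def _pairwise_distances(tree: PhyloTree) -> np.ndarray:
    """All-pairs path lengths on the (undirected) tree."""
    n = tree.n_nodes
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i in range(n):
        p = tree.parent[i]
        if p >= 0:
            ln = float(tree.edge_length[i])
            adj[i].append((p, ln))
            adj[p].append((i, ln))
    dist = np.full((n, n), np.inf)
    for src in range(n):
        dist[src, src] = 0.0
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if dist[src, v] == np.inf:
                    dist[src, v] = dist[src, u] + ln
                    stack.append(v)
    return dist


def gls_ancestral_state(tree: PhyloTree, tip_values: dict, focal: int) -> float:
    """GLS/ML state at ``focal``: with the tree re-rooted at the focal node,
    tip covariance V_ij is the shared path length from the focal node, and the
    estimate is (1' V^-1 x) / (1' V^-1 1)."""
    dist = _pairwise_distances(tree)
    tips = tree.tip_indices
    x = np.array([tip_values[tree.labels[i]] for i in tips], dtype=float)
    m = len(tips)
    V = np.empty((m, m))
    for a, i in enumerate(tips):
        for b, j in enumerate(tips):
            V[a, b] = 0.5 * (dist[focal, i] + dist[focal, j] - dist[i, j])
    ones = np.ones(m)
    Vinv_x = np.linalg.solve(V, x)
    Vinv_1 = np.linalg.solve(V, ones)
    return float(ones @ Vinv_x / (ones @ Vinv_1))


def golden_section_ma_slope(x, y, through_origin: bool = True, tol: float = 1e-9) -> float:
    """MA slope by golden-section search over the line angle.

    Minimizes the total perpendicular squared distance of the points to a line
    through the origin (of the centered cloud, unless ``through_origin``) with
    direction (cos t, sin t). The objective is A + B cos 2t + C sin 2t, so a
    coarse bracket plus golden-section localizes the unique minimum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not through_origin:
        x = x - x.mean()
        y = y - y.mean()
    total = x @ x + y @ y

    def perp_ss(t: float) -> float:
        u = np.array([math.cos(t), math.sin(t)])
        proj = x * u[0] + y * u[1]
        return float(total - proj @ proj)

    grid = np.linspace(-math.pi / 2, math.pi / 2, 721)
    vals = [perp_ss(t) for t in grid]
    k = int(np.argmin(vals))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    invphi = (math.sqrt(5) - 1) / 2
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = perp_ss(c), perp_ss(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = perp_ss(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = perp_ss(d)
    return math.tan((a + b) / 2)
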