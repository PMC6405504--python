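"""ML ancestral reconstruction of a continuous trait under Brownian motion.

The maximum-likelihood state at an internal node equals the root estimate of
the contrasts recursion after re-rooting the tree at that node (equivalently,
the GLS estimate under the BM tip covariance — the two are checked against
each other in the test suite). Re-rooting is done implicitly: the tree is
treated as an undirected graph and, for each focal node, trait information is
"peeled" inward from every neighbour; each peel returns a (value, variance)
summary and the focal estimate is their precision-weighted mean. States along
a branch are linear between the endpoint estimates, which under BM coincides
with the ML value at interior points; the painted-tree export colours branches
by these interpolated states on a diverging ramp centred at zero (so the sign
of a dimorphism index is immediately readable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contrasts import compute_contrasts, estimate_bm_rate
from .phylo_io import PhyloTree


@dataclass
class AncestralMap:
    """States at every node (observed at tips, ML estimates at internal
    nodes), plus the tree they live on and the BM rate estimated from the
    contrasts (recorded for reference; point estimates are scale-free)."""

    tree: PhyloTree
    states: np.ndarray  # indexed by node id
    trait: str = "trait"
    sigma2: float = np.nan

    def state(self, node: int) -> float:
        return float(self.states[node])

    def node_frame(self):
        import pandas as pd

        rows = [
            {
                "node_id": i,
                "label": self.tree.labels[i] or "",
                "is_tip": self.tree.is_tip(i),
                "state": float(self.states[i]),
            }
            for i in self.tree.postorder()
        ]
        return pd.DataFrame(rows).sort_values("node_id").reset_index(drop=True)


def _neighbors(tree: PhyloTree) -> list[list[tuple[int, float]]]:
    nb: list[list[tuple[int, float]]] = [[] for _ in range(tree.n_nodes)]
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p >= 0:
            ln = float(tree.edge_length[i])
            nb[i].append((p, ln))
            nb[p].append((i, ln))
    return nb


def _peel_all(tree: PhyloTree, x: np.ndarray, focal: int, nb) -> list[tuple[float, float]]:
    """For each neighbour edge of ``focal``, peel the subtree on the far side
    down to a (value, variance) pair at the focal end of that edge."""

    # iterative post-order on the tree re-rooted at `focal`
    order: list[tuple[int, int]] = []  # (node, parent-in-rerooted-sense)
    stack = [(focal, -1)]
    while stack:
        node, par = stack.pop()
        order.append((node, par))
        for other, _ in nb[node]:
            if other != par:
                stack.append((other, node))

    val = np.full(tree.n_nodes, np.nan)
    var = np.full(tree.n_nodes, np.nan)  # extra variance accumulated at the node
    for node, par in reversed(order):
        kids = [(o, ln) for o, ln in nb[node] if o != par]
        if node != focal and not kids:  # tip (in the re-rooted sense)
            val[node], var[node] = x[node], 0.0
            continue
        if node == focal:
            continue
        wsum = vsum = 0.0
        for o, ln in kids:
            v = var[o] + ln
            if v <= 0:
                val[node], var[node] = val[o], 0.0
                break
            wsum += val[o] / v
            vsum += 1.0 / v
        else:
            val[node] = wsum / vsum
            var[node] = 1.0 / vsum
    return [(float(val[o] if not np.isnan(val[o]) else x[o]), float((0.0 if np.isnan(var[o]) else var[o]) + ln)) for o, ln in nb[focal]]


def ml_ancestral_states(tree: PhyloTree, tip_values, trait: str = "trait", log10_flag: bool = False) -> AncestralMap:
    """ML states at all internal nodes under BM (re-rooted contrasts).

    Requires >= 2 tips with values for every tip; zero-length branches (from
    resolved polytomies) are allowed as long as no node becomes completely
    disconnected in time.
    """
    if tree.n_tips < 2:
        raise ValueError("ancestral reconstruction needs >= 2 tips")
    from .contrasts import _tip_value_array

    x = _tip_value_array(tree, tip_values)
    tip_idx = tree.tip_indices
    if log10_flag:
        if np.any(x[tip_idx] <= 0):
            raise ValueError("log10 transform requires positive tip values")
        x[tip_idx] = np.log10(x[tip_idx])
    nb = _neighbors(tree)
    states = x.copy()
    for node in range(tree.n_nodes):
        if tree.is_tip(node):
            continue
        parts = _peel_all(tree, x, node, nb)
        wsum = vsum = 0.0
        pinned = None
        for val, v in parts:
            if v <= 0:
                pinned = val
                break
            wsum += val / v
            vsum += 1.0 / v
        states[node] = pinned if pinned is not None else wsum / vsum
    sigma2 = np.nan
    if tree.is_binary:
        cs = compute_contrasts(tree, tip_values, log10_flag=log10_flag, trait=trait)
        sigma2 = estimate_bm_rate(cs)
    return AncestralMap(tree=tree, states=states, trait=trait, sigma2=sigma2)


def interpolate_branch(anc_map: AncestralMap, edge: int, t: float) -> float:
    """State at position ``t`` (time from the parent end) along the branch
    above node ``edge``. Linear between the endpoint estimates; a zero-length
    edge returns the child state."""
    tree = anc_map.tree
    if edge == tree.root or tree.parent[edge] < 0:
        raise ValueError("root has no parent branch")
    length = float(tree.edge_length[edge])
    if not (0.0 <= t <= length or (length == 0 and t == 0)):
        raise ValueError(f"t={t} outside [0, {length}]")
    child = anc_map.state(edge)
    if length == 0:
        return child
    parent = anc_map.state(tree.parent[edge])
    return parent + (t / length) * (child - parent)


def paint_tree(anc_map: AncestralMap, color_ramp: str = "RdYlBu", segments: int = 24, ax=None):
    """Phylogram with branches coloured by the interpolated trait state.

    Uses a diverging ramp centred at state 0 (negative = one direction of
    bias, positive = the other). Degenerate (constant) reconstructions paint
    a single colour with a warning. Returns the matplotlib Figure.
    """
    import warnings

    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection
    from matplotlib.colors import TwoSlopeNorm

    tree = anc_map.tree
    depths = tree.depths()
    ypos = np.zeros(tree.n_nodes)
    y = 0.0
    for i in tree.postorder():
        if tree.is_tip(i):
            ypos[i] = y
            y += 1.0
    for i in tree.postorder():
        if not tree.is_tip(i):
            ypos[i] = np.mean([ypos[c] for c in tree.children[i]])

    lo, hi = float(anc_map.states.min()), float(anc_map.states.max())
    if lo == hi:
        warnings.warn("constant ancestral states: painting a single colour")
        lo, hi = lo - 0.5, hi + 0.5
    vmax = max(abs(lo), abs(hi), 1e-12)
    norm = TwoSlopeNorm(vmin=-vmax, vcenter=0.0, vmax=vmax)
    cmap = plt.get_cmap(color_ramp)

    if ax is None:
        fig, ax = plt.subplots(figsize=(7, max(3, tree.n_tips * 0.22)))
    else:
        fig = ax.figure
    segs, colors = [], []
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p < 0:
            continue
        x0, x1 = depths[p], depths[i]
        length = float(tree.edge_length[i])
        for k in range(segments):
            f0, f1 = k / segments, (k + 1) / segments
            s_mid = interpolate_branch(anc_map, i, length * (f0 + f1) / 2) if length > 0 else anc_map.state(i)
            segs.append([(x0 + (x1 - x0) * f0, ypos[i]), (x0 + (x1 - x0) * f1, ypos[i])])
            colors.append(cmap(norm(s_mid)))
        segs.append([(x0, ypos[p]), (x0, ypos[i])])
        colors.append(cmap(norm(anc_map.state(p))))
    ax.add_collection(LineCollection(segs, colors=colors, linewidths=2))
    for i in tree.tip_indices:
        ax.text(depths[i] + 0.01 * depths.max(), ypos[i], tree.labels[i] or "", va="center", fontsize=7, style="italic")
    ax.set_xlim(0, depths.max() * 1.35)
    ax.set_ylim(-1, tree.n_tips)
    ax.set_yticks([])
    ax.set_xlabel("time")
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=ax, label=anc_map.trait, shrink=0.6)
    return fig
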