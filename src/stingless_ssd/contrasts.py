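"""Phylogenetic independent contrasts (Felsenstein's method).

Under Brownian motion with rate sigma^2, the standardized contrasts

    C_k = (x_i - x_j) / sqrt(v_i + v_j)

computed in a single post-order pass are iid Normal(0, sigma^2): at each
internal node the two child values (tip observations or nodal estimates) are
differenced and standardized by the square root of the summed (adjusted)
branch lengths; the nodal estimate is the branch-length-weighted mean

    x_hat = (x_i / v_i + x_j / v_j) / (1/v_i + 1/v_j)

and the node's own parent branch is lengthened by v_i * v_j / (v_i + v_j) to
account for the estimation error in x_hat. Child order follows the tree's
canonical ordering (smallest descendant tip label first), so the sign
convention is stable across traits on the same tree and bivariate contrast
pairs stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_io import PhyloTree


class PolytomyError(ValueError):
    """Non-binary tree; resolve with phylo_io.resolve_polytomies first."""


@dataclass
class ContrastSet:
    """Contrasts in deterministic post-order over internal nodes.

    ``node_ids[k]`` is the internal-node index the k-th contrast belongs to;
    ``sds[k] = sqrt(v_i + v_j)`` its standard-deviation scale (time^0.5);
    ``nodal_values[k]`` the weighted ancestral estimate at that node; and
    ``adjusted_lengths[k]`` the node's parent branch length after lengthening
    (NaN at the root).
    """

    node_ids: np.ndarray
    contrasts: np.ndarray
    sds: np.ndarray
    nodal_values: np.ndarray
    adjusted_lengths: np.ndarray
    trait: str = "trait"
    log10_applied: bool = False
    root_value: float = field(default=np.nan)

    @property
    def n(self) -> int:
        return len(self.contrasts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "contrast": self.contrasts,
                "sd": self.sds,
                "nodal_value": self.nodal_values,
            }
        )


def _tip_value_array(tree: PhyloTree, tip_values) -> np.ndarray:
    vals = np.full(tree.n_nodes, np.nan)
    mapping = dict(tip_values.items()) if hasattr(tip_values, "items") else dict(tip_values)
    missing = [t for t in tree.tip_labels if t not in mapping]
    if missing:
        raise ValueError(f"missing tip values for: {sorted(missing)}")
    for i in tree.tip_indices:
        vals[i] = float(mapping[tree.labels[i]])
    return vals


def compute_contrasts(tree: PhyloTree, tip_values, log10_flag: bool = False, trait: str = "trait") -> ContrastSet:
    """Standardized contrasts of one trait on a binary tree.

    ``tip_values`` maps tip label -> value (a dict or pandas Series). With
    ``log10_flag`` the values are log10-transformed first (all must be > 0).
    """
    if not tree.is_binary:
        raise PolytomyError(
            "contrasts require a binary tree; use phylo_io.resolve_polytomies"
        )
    x = _tip_value_array(tree, tip_values)
    if log10_flag:
        tip_idx = tree.tip_indices
        if np.any(x[tip_idx] <= 0):
            raise ValueError("log10 transform requires all tip values > 0")
        x[tip_idx] = np.log10(x[tip_idx])

    v = tree.edge_length.astype(float).copy()  # adjusted branch lengths
    node_ids, contrasts, sds, nodals = [], [], [], []
    for i in tree.postorder():
        if tree.is_tip(i):
            continue
        ci, cj = tree.children[i]
        vi, vj = v[ci], v[cj]
        vsum = vi + vj
        if vsum <= 0:
            raise ValueError(
                f"zero contrast variance at node {i}: both child branches have length 0"
            )
        node_ids.append(i)
        contrasts.append((x[ci] - x[cj]) / np.sqrt(vsum))
        sds.append(np.sqrt(vsum))
        x[i] = (x[ci] / vi + x[cj] / vj) / (1.0 / vi + 1.0 / vj) if vi > 0 and vj > 0 else (
            x[ci] if vi == 0 else x[cj]
        )
        nodals.append(x[i])
        if i != tree.root:
            v[i] = v[i] + vi * vj / vsum
    adj = np.array([v[i] if i != tree.root else np.nan for i in node_ids])
    return ContrastSet(
        node_ids=np.array(node_ids),
        contrasts=np.array(contrasts),
        sds=np.array(sds),
        nodal_values=np.array(nodals),
        adjusted_lengths=adj,
        trait=trait,
        log10_applied=log10_flag,
        root_value=float(x[tree.root]),
    )


def estimate_bm_rate(contrast_set: ContrastSet) -> float:
    """Brownian-motion rate estimate: mean of squared standardized contrasts."""
    if contrast_set.n == 0:
        raise ValueError("empty contrast set")
    return float(np.mean(contrast_set.contrasts**2))
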