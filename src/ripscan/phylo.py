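"""Phylogenetically independent contrasts (PIC) and through-origin contrast
regression.

Under Brownian-motion trait evolution on a rooted tree, the standardized
contrast at an internal node with children values x_L, x_R on branches of
(expected-variance) lengths v_L, v_R is

    c = (x_L - x_R) / sqrt(v_L + v_R),

the ancestral value is the precision-weighted mean of the children, and the
node's own branch is inflated by v_L * v_R / (v_L + v_R). On a binary tree
with n tips this yields n - 1 contrasts that are independent and
identically distributed N(0, sigma^2), which licenses ordinary regression
*through the origin* between the contrasts of two traits — contrasts have
arbitrary sign, so the model has no intercept.

Polytomies are resolved arbitrarily into zero-length bifurcations (logged),
and zero or missing branch lengths are replaced by a small epsilon to keep
the recursion defined.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastSet",
    "load_tree",
    "pic",
    "contrast_regression",
    "fdr_adjust",
    "log10_with_zeros",
]


@dataclass
class ContrastSet:
    """Standardized contrasts, one per internal node of a binary tree."""

    contrasts: np.ndarray
    node_ids: List[str]
    n_tips: int

    def __len__(self) -> int:
        return self.contrasts.size


def load_tree(source: str) -> dendropy.Tree:
    """Load a rooted newick tree from a path or a newick string."""
    if "(" in source:
        tree = dendropy.Tree.get(data=source, schema="newick")
    else:
        tree = dendropy.Tree.get(path=source, schema="newick")
    tree.is_rooted = True
    return tree


def _prepare(tree: dendropy.Tree, epsilon: float) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    polytomies = [
        n for n in tree.preorder_node_iter() if len(n.child_nodes()) > 2
    ]
    if polytomies:
        logger.warning(
            "resolving %d polytomies with zero-length branches", len(polytomies)
        )
        tree.resolve_polytomies()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            edge.length = epsilon
    return tree


def pic(
    tree: dendropy.Tree | str,
    trait: Mapping[str, float],
    epsilon: float = 1e-8,
) -> ContrastSet:
    """Felsenstein's phylogenetically independent contrasts.

    ``trait`` maps tip labels to values; every tip must have a value.
    Returns one standardized contrast per internal node, in postorder.
    """
    if isinstance(tree, str):
        tree = load_tree(tree)
    tree = _prepare(tree, epsilon)

    values: Dict[int, float] = {}
    lengths: Dict[int, float] = {}
    contrasts: List[float] = []
    node_ids: List[str] = []
    n_tips = 0

    for i, node in enumerate(tree.postorder_node_iter()):
        node._pic_id = i

    for node in tree.postorder_node_iter():
        edge_len = node.edge.length if node.edge.length is not None else 0.0
        if node.is_leaf():
            n_tips += 1
            label = node.taxon.label if node.taxon else None
            if label is None or label not in trait:
                raise ValueError(f"missing trait value for tip {label!r}")
            values[node._pic_id] = float(trait[label])
            lengths[node._pic_id] = float(edge_len)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError(
                f"unresolved polytomy at node with {len(children)} children"
            )
        l, r = children
        xl, xr = values[l._pic_id], values[r._pic_id]
        vl, vr = lengths[l._pic_id], lengths[r._pic_id]
        contrasts.append((xl - xr) / np.sqrt(vl + vr))
        node_ids.append(node.label or f"node{node._pic_id}")
        values[node._pic_id] = (xl / vl + xr / vr) / (1.0 / vl + 1.0 / vr)
        lengths[node._pic_id] = float(edge_len) + vl * vr / (vl + vr)

    return ContrastSet(
        contrasts=np.asarray(contrasts, dtype=float),
        node_ids=node_ids,
        n_tips=n_tips,
    )


def contrast_regression(
    cx: ContrastSet | np.ndarray, cy: ContrastSet | np.ndarray
) -> Tuple[float, float, float]:
    """Least-squares through the origin of cy on cx.

    Returns (slope, adjusted R^2, two-sided p-value for the slope). The
    two contrast sets must come from the same tree in the same node order.
    """
    x = cx.contrasts if isinstance(cx, ContrastSet) else np.asarray(cx, float)
    y = cy.contrasts if isinstance(cy, ContrastSet) else np.asarray(cy, float)
    if x.size != y.size:
        raise ValueError("contrast sets differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 contrasts for regression")
    fit = sm.OLS(y, x[:, None]).fit()
    return float(fit.params[0]), float(fit.rsquared_adj), float(fit.pvalues[0])


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log10_with_zeros(values: pd.Series | np.ndarray) -> np.ndarray:
    """log10 transform keeping exact zeros as 0.

    This mirrors a common (if discontinuous) treatment of zero-valued
    genome metrics before contrast analysis; prefer log10(x + 1) when the
    mixed scale is a concern.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    out = np.zeros_like(v)
    nz = v > 0
    out[nz] = np.log10(v[nz])
    return out
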