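"""Summary statistics of reconstructed trees.

- species richness (SR): number of tips;
- the Pybus-Harvey ``gamma`` statistic, standardised against the pure-birth
  expectation (negative values mean nodes concentrated near the root, i.e.
  long terminal branches);
- the ``stairs2`` balance index: mean over internal nodes of the ratio of
  the smaller to the larger child-subtree tip count (topology only, in
  ``(0, 1]``);
- the ``DR`` tip rate: the inverse equal-splits measure, a per-tip proxy for
  the speciation rate at the present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .trees import ReconstructedTree


def gamma_statistic(tree: ReconstructedTree, ultrametric_rel_tol: float = 1e-6) -> float:
    """Pybus-Harvey gamma from the internode intervals of an ultrametric tree.

    With ``g_k`` the duration during which exactly ``k`` lineages exist
    (``k = 2..n``) and ``S = sum_k k*g_k`` the total branch length of the
    reconstructed process,

    .. math::

        \\gamma = \\frac{\\frac{1}{n-2}\\sum_{i=2}^{n-1}\\sum_{k=2}^{i} k g_k
                         - S/2}{S \\sqrt{1 / (12 (n - 2))}}

    Requires ``n >= 3`` tips.
    """
    n = tree.n_tips
    if n < 3:
        raise ValueError(f"gamma requires >= 3 tips, got {n}")
    if not tree.is_ultrametric(ultrametric_rel_tol):
        raise ValueError("gamma requires an ultrametric tree")
    ages = tree.branching_ages()  # descending, len n-1
    # lineage count is k on the interval [ages[k-1], ages[k-2]) going rootward;
    # g_k = ages[k-2] - ages[k-1] for k = 2..n-1, g_n = ages[n-2] (to present)
    bounds = ages + [0.0]
    g = np.array([bounds[k - 2] - bounds[k - 1] for k in range(2, n + 1)])
    ks = np.arange(2, n + 1)
    kg = ks * g
    S = kg.sum()
    if S <= 0:
        raise ValueError("tree has zero total depth")
    cum = np.cumsum(kg)  # cum[i-2] = sum_{k=2}^{i} k g_k
    num = cum[: n - 2].sum() / (n - 2) - S / 2.0
    return float(num / (S * math.sqrt(1.0 / (12.0 * (n - 2)))))


def _tip_counts(tree: ReconstructedTree) -> dict:
    counts = {}
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            counts[nd] = 1
        else:
            counts[nd] = sum(counts[c] for c in nd.child_nodes())
    return counts


def stairs2(tree: ReconstructedTree) -> float:
    """Mean ratio of smaller to larger child-subtree size over internal nodes.

    Topology-only balance index in ``(0, 1]``; 1 for fully balanced trees.
    A two-tip tree (single cherry) scores 1.
    """
    if tree.n_tips < 2:
        raise ValueError("stairs2 requires >= 2 tips")
    counts = _tip_counts(tree)
    ratios = []
    for nd in tree.dendropy_tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        kids = nd.child_nodes()
        if len(kids) != 2:
            raise ValueError("stairs2 requires a binary tree")
        a, b = counts[kids[0]], counts[kids[1]]
        ratios.append(min(a, b) / max(a, b))
    return float(np.mean(ratios))


def dr_statistic(tree: ReconstructedTree) -> tuple[dict[str, float], float]:
    """Per-tip DR values (inverse equal-splits measure) and their median.

    For tip ``i`` with edge lengths ``l_1, ..., l_N`` along the path from the
    tip (``l_1`` = pendant edge) to the root,

    .. math:: DR_i = \\Big[ \\sum_{j=1}^{N} l_j \\, (1/2)^{j-1} \\Big]^{-1}

    so the pendant edge carries full weight and each step rootward halves it.
    """
    values: dict[str, float] = {}
    for leaf in tree.leaf_iter():
        s = 0.0
        w = 1.0
        nd = leaf
        while nd.parent_node is not None:
            s += (nd.edge.length or 0.0) * w
            w *= 0.5
            nd = nd.parent_node
        if s <= 0:
            raise ValueError(f"zero root-to-tip path length at tip {leaf.taxon.label!r}")
        values[leaf.taxon.label if leaf.taxon else str(id(leaf))] = 1.0 / s
    return values, float(np.median(list(values.values())))


@dataclass
class TreeStats:
    sr: int
    gamma: Optional[float]
    stairs2: Optional[float]
    dr_median: Optional[float]


def tree_stats(tree: ReconstructedTree) -> TreeStats:
    """All summary statistics for one tree; gamma is ``None`` for SR < 3."""
    n = tree.n_tips
    g = gamma_statistic(tree) if n >= 3 else None
    s2 = stairs2(tree) if n >= 2 else None
    dr = dr_statistic(tree)[1] if n >= 1 and tree.height > 0 else None
    return TreeStats(sr=n, gamma=g, stairs2=s2, dr_median=dr)


def batch_stats(batch) -> pd.DataFrame:
    """Per-replicate statistics table for a :class:`ReplicateBatch`.

    One row per replicate (invalid replicates carry NaN statistics and
    ``valid = False``); use :func:`summarize_stats` for the median/quartile
    summary.
    """
    rows = []
    for i, tree in enumerate(batch.trees):
        if tree is None:
            rows.append(
                {"replicate": i, "valid": False, "sr": np.nan, "gamma": np.nan,
                 "stairs2": np.nan, "dr_median": np.nan}
            )
            continue
        st = tree_stats(tree)
        rows.append(
            {
                "replicate": i,
                "valid": True,
                "sr": st.sr,
                "gamma": st.gamma if st.gamma is not None else np.nan,
                "stairs2": st.stairs2 if st.stairs2 is not None else np.nan,
                "dr_median": st.dr_median if st.dr_median is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles per statistic across the valid replicates."""
    out = []
    for col in ("sr", "gamma", "stairs2", "dr_median"):
        vals = table.loc[table["valid"], col].dropna()
        out.append(
            {
                "statistic": col,
                "n_valid": int(vals.size),
                "q1": float(vals.quantile(0.25)) if vals.size else np.nan,
                "median": float(vals.median()) if vals.size else np.nan,
                "q3": float(vals.quantile(0.75)) if vals.size else np.nan,
            }
        )
    return pd.DataFrame(out)
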