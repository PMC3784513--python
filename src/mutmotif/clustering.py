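"""Dataset comparison by context spectra: Manhattan distances, agglomerative
clustering, and bootstrap cluster support.

Rows of a spectrum matrix are datasets (or samples) and columns are motif or
trimer classes, each row scaled to unit sum.  Distances are city-block
(Manhattan) sums of absolute differences; clusters from the agglomerative
merge tree are annotated with the fraction of column-resampled bootstrap
replicates that reproduce their exact leaf membership, and memberships with
support at or above a threshold (default 0.90) are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .fractions import FractionTable
from .physchem import aggregate_to_trimers

__all__ = [
    "spectrum_matrix",
    "manhattan_matrix",
    "cluster",
    "ClusterResult",
]


def spectrum_matrix(
    tables: Mapping[str, FractionTable], level: str = "tetramer"
) -> pd.DataFrame:
    """Row-stochastic matrix of mutated-motif fractions across datasets.

    ``level="trimer"`` first sums tetramer counts over P4 within each NGN
    stem.  Rows whose fractions are all zero or undefined are excluded with a
    warning; remaining rows are scaled to unit sum.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 datasets to build a spectrum matrix")
    rows = {}
    for name, ft in tables.items():
        if level == "tetramer":
            f = ft.table["f"]
        elif level == "trimer":
            f = aggregate_to_trimers(ft)["f"]
        else:
            raise ValueError(f"unknown level {level!r}")
        f = f.fillna(0.0)
        total = f.sum()
        if total <= 0:
            warnings.warn(f"dataset {name!r} has an all-zero spectrum; excluded")
            continue
        rows[name] = f / total
    if len(rows) < 2:
        raise ValueError("fewer than 2 usable rows after exclusions")
    return pd.DataFrame(rows).T


def manhattan_matrix(sm: pd.DataFrame) -> pd.DataFrame:
    """Symmetric all-to-all city-block distance matrix between rows."""
    if len(sm) < 2:
        raise ValueError("need at least 2 rows")
    dist = squareform(pdist(sm.to_numpy(), metric="cityblock"))
    return pd.DataFrame(dist, index=sm.index, columns=sm.index)


@dataclass
class ClusterResult:
    """Agglomerative merge tree with bootstrap support per internal node."""

    linkage_matrix: np.ndarray
    labels: list[str]
    supports: pd.DataFrame  # members (frozenset), height, support, supported
    newick: str
    support_threshold: float = 0.90

    @property
    def supported_clusters(self) -> list[frozenset]:
        return list(self.supports.loc[self.supports["supported"], "members"])


def _node_memberships(Z: np.ndarray, labels: list[str]) -> list[tuple[frozenset, float]]:
    """Leaf-label membership set and merge height of every internal node."""
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for k, (a, b, height, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        out.append((merged, float(height)))
    return out


def _to_newick(Z: np.ndarray, labels: list[str], support: dict[frozenset, float]) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        leaf_ids = node.pre_order(lambda leaf: leaf.id)
        key = frozenset(labels[i] for i in leaf_ids)
        sup = support.get(key)
        label = f"{sup:.2f}" if sup is not None else ""
        return f"({left},{right}){label}:{length:g}"

    return walk(tree, tree.dist) + ";"


def cluster(
    data: pd.DataFrame,
    linkage: str = "average",
    bootstrap_b: int = 1000,
    seed: int | None = None,
    support_threshold: float = 0.90,
) -> ClusterResult:
    """Agglomerative clustering of spectrum rows with bootstrap support.

    Support of an internal node is the fraction of ``bootstrap_b`` replicates
    (columns resampled with replacement, distances and tree recomputed) whose
    merge tree contains a node with the identical leaf membership; the root
    (all rows) always has support 1.  Fully reproducible for a fixed
    (bootstrap_b, seed).
    """
    if linkage not in ("average", "single", "complete"):
        raise ValueError("linkage must be one of average/single/complete")
    if len(data) < 3:
        raise ValueError("need at least 3 rows for meaningful clusters")
    if bootstrap_b < 100:
        warnings.warn(f"bootstrap_b={bootstrap_b} is small; supports will be noisy")

    labels = list(map(str, data.index))
    X = data.to_numpy(dtype=float)
    Z = hierarchy.linkage(pdist(X, metric="cityblock"), method=linkage)
    nodes = _node_memberships(Z, labels)

    counts = {members: 0 for members, _ in nodes}
    rng = np.random.default_rng(seed)
    n_cols = X.shape[1]
    for _ in range(bootstrap_b):
        cols = rng.integers(0, n_cols, size=n_cols)
        Zb = hierarchy.linkage(pdist(X[:, cols], metric="cityblock"), method=linkage)
        seen = {members for members, _ in _node_memberships(Zb, labels)}
        for members in counts:
            if members in seen:
                counts[members] += 1

    support = {m: counts[m] / bootstrap_b if bootstrap_b else np.nan for m in counts}
    table = pd.DataFrame(
        {
            "members": [m for m, _ in nodes],
            "size": [len(m) for m, _ in nodes],
            "height": [h for _, h in nodes],
            "support": [support[m] for m, _ in nodes],
        }
    )
    table["supported"] = table["support"] >= support_threshold
    return ClusterResult(
        linkage_matrix=Z,
        labels=labels,
        supports=table,
        newick=_to_newick(Z, labels, support),
        support_threshold=support_threshold,
    )
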