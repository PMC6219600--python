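"""Correlation-distance UPGMA clustering of SNP score matrices.

Pearson's correlation coefficient r between two samples' raw 0/1/2 score
vectors serves as the similarity index; it is transformed to a genetic
distance with d = 100(1 - r), so identical samples sit at d = 0 and
perfectly anti-correlated ones at d = 200. Trees are built with classical
(cluster-size-weighted average linkage) UPGMA; node height is half the
merge distance, making the tree ultrametric on the d scale.

Ties in the merge order are broken lexicographically on the clusters'
sorted leaf labels, so the output is reproducible regardless of input
order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SnpMatrix

PAIRWISE_POLICIES = ("pairwise", "listwise")


class DistanceError(ValueError):
    """Pearson r undefined (constant vector) or insufficient overlap."""


@dataclass
class DistanceMatrix:
    """Symmetric d = 100(1 - r) matrix with the r matrix retained for audit."""

    d: pd.DataFrame
    r: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.d.index)

    def to_csv(self, path: str | Path) -> None:
        self.d.rename_axis("sample").to_csv(path)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson r; NaN when either vector is constant."""
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm * xm).sum() * (ym * ym).sum())
    if denom == 0.0:
        return np.nan
    return float((xm * ym).sum() / denom)


def correlation_distance(
    snp_matrix: SnpMatrix,
    sample_subset: Sequence[str] | None = None,
    pairwise_policy: str = "pairwise",
) -> DistanceMatrix:
    """Pairwise Pearson r over raw SNP scores, transformed to d = 100(1 - r).

    ``pairwise`` (default) computes each pair's r over the markers
    non-missing in both samples; ``listwise`` first drops every marker with
    any missing call. Each pair must share at least 2 complete markers, and
    a constant score vector over the shared markers makes r undefined —
    both raise, naming the offending pair.
    """
    if pairwise_policy not in PAIRWISE_POLICIES:
        raise ValueError(f"pairwise_policy must be one of {PAIRWISE_POLICIES}")
    samples = list(sample_subset) if sample_subset is not None else snp_matrix.sample_ids
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    scores = snp_matrix.scores[samples]
    if pairwise_policy == "listwise":
        scores = scores.dropna(axis=0, how="any")
    data = scores.to_numpy(dtype=float)
    n = len(samples)
    r = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        xi, xj = data[:, i], data[:, j]
        complete = ~np.isnan(xi) & ~np.isnan(xj)
        if complete.sum() < 2:
            raise DistanceError(
                f"samples {samples[i]!r} and {samples[j]!r} share only "
                f"{int(complete.sum())} complete markers (need >= 2)"
            )
        rij = _pearson(xi[complete], xj[complete])
        if np.isnan(rij):
            raise DistanceError(
                f"Pearson r undefined for samples {samples[i]!r} and {samples[j]!r}: "
                "constant score vector over their shared markers"
            )
        r[i, j] = r[j, i] = rij
    r_df = pd.DataFrame(r, index=samples, columns=samples)
    d_df = 100.0 * (1.0 - r_df)
    np.fill_diagonal(d_df.values, 0.0)
    return DistanceMatrix(d=d_df, r=r_df)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree; height 0 at the leaves."""

    height: float
    label: str | None = None
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [leaf for child in self.children for leaf in child.leaves()]


@dataclass
class UpgmaTree:
    """Rooted binary ultrametric tree with its merge order retained."""

    root: TreeNode
    merge_order: list = field(default_factory=list)  # (leafset_a, leafset_b, height)

    @property
    def leaf_labels(self) -> list[str]:
        return self.root.leaves()

    def height_of_ancestor(self, a: str, b: str) -> float:
        """Height of the most recent common ancestor of two leaves."""
        node = self.root
        while not node.is_leaf:
            for child in node.children:
                lv = set(child.leaves())
                if a in lv and b in lv:
                    node = child
                    break
            else:
                return node.height
        return node.height


def upgma(distance: DistanceMatrix | pd.DataFrame, tie_rule: str = "lexicographic") -> UpgmaTree:
    """Classical UPGMA (cluster-size-weighted average linkage).

    The pair at minimum distance merges at height d/2; tied minima are
    resolved by the lexicographically smallest pair of concatenated sorted
    leaf labels. Distances between the new cluster and the rest follow the
    Lance-Williams update d_new,k = (n_i d_ik + n_j d_jk) / (n_i + n_j).
    """
    if tie_rule != "lexicographic":
        raise ValueError("only the 'lexicographic' tie rule is implemented")
    d_df = distance.d if isinstance(distance, DistanceMatrix) else distance
    if not np.isfinite(d_df.to_numpy(dtype=float)).all():
        raise ValueError("distance matrix contains non-finite values")
    labels = list(d_df.index)
    if len(labels) == 1:
        return UpgmaTree(root=TreeNode(height=0.0, label=labels[0]))
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=lab) for i, lab in enumerate(labels)
    }
    sizes = {i: 1 for i in nodes}
    keys = {i: "".join(sorted(nodes[i].leaves())) for i in nodes}
    dist: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(len(labels)), 2):
        dist[(i, j)] = float(d_df.iloc[i, j])
    merges = []
    next_id = len(labels)
    while len(nodes) > 1:
        live = sorted(nodes)
        best = None
        for i, j in itertools.combinations(live, 2):
            dij = dist[(min(i, j), max(i, j))]
            tie_key = tuple(sorted((keys[i], keys[j])))
            cand = (dij, tie_key, (i, j))
            if best is None or cand < best:
                best = cand
        dij, _, (i, j) = best
        height = dij / 2.0
        ni, nj = sizes[i], sizes[j]
        # children ordered lexicographically for a canonical serialization
        kids = sorted((nodes[i], nodes[j]), key=lambda nd: "".join(sorted(nd.leaves())))
        parent = TreeNode(height=height, children=tuple(kids))
        merges.append((sorted(nodes[i].leaves()), sorted(nodes[j].leaves()), height))
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(next_id, k), max(next_id, k))] = (ni * dik + nj * djk) / (ni + nj)
        for k in (i, j):
            del nodes[k], sizes[k], keys[k]
        nodes[next_id] = parent
        sizes[next_id] = ni + nj
        keys[next_id] = "".join(sorted(parent.leaves()))
        next_id += 1
    return UpgmaTree(root=nodes.popitem()[1], merge_order=merges)


# ---------------------------------------------------------------------------
# Newick serialization
# ---------------------------------------------------------------------------

_NEWICK_RESERVED = set(" ,():;'[]")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_RESERVED for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_length(x: float) -> str:
    return f"{x:.12g}"


def _node_newick(node: TreeNode, parent_height: float) -> str:
    branch = _fmt_length(parent_height - node.height)
    if node.is_leaf:
        return f"{_quote(node.label)}:{branch}"
    inner = ",".join(_node_newick(c, node.height) for c in node.children)
    return f"({inner}):{branch}"


def to_newick(tree: UpgmaTree) -> str:
    """Newick string with branch lengths on the d scale."""
    root = tree.root
    if root.is_leaf:
        return f"{_quote(root.label)}:0;"
    inner = ",".join(_node_newick(c, root.height) for c in root.children)
    return f"({inner});"


def write_newick(tree: UpgmaTree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")
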