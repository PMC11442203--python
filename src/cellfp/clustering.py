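"""Agglomerative hierarchical clustering on the compound distance matrix.

The agglomeration is an explicit Lance–Williams loop rather than a call
into scipy so that tie-breaking is fully specified: when several cluster
pairs attain the minimal distance, the pair whose (lexicographically
smallest member id, then second-smallest representative) sorts first is
merged.  On distance matrices without exact ties the merge sequence
coincides with scipy's; the O(n³) cost is irrelevant at the few hundred
compounds this pipeline handles.

Supported linkages: complete (default — the default criterion of the
clustering this mirrors), average (UPGMA), single, and ward (via the
Lance–Williams update on squared distances; merge heights are reported on
the distance scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

LINKAGES = ("complete", "average", "single", "ward")


@dataclass
class Dendrogram:
    """Merge tree in scipy convention: leaves are nodes 0..n−1, the i-th
    merge creates node n+i joining nodes ``merges[i][0]`` and
    ``merges[i][1]`` at height ``merges[i][2]``."""

    ids: list[str]
    merges: list[tuple[int, int, float]]
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def to_scipy(self) -> np.ndarray:
        """Linkage matrix Z compatible with scipy.cluster.hierarchy."""
        n = self.n_leaves
        sizes: dict[int, int] = {i: 1 for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for i, (a, b, h) in enumerate(self.merges):
            sizes[n + i] = sizes[a] + sizes[b]
            Z[i] = [a, b, h, sizes[n + i]]
        return Z

    def node_min_leaf(self) -> dict[int, str]:
        """Lexicographically smallest leaf id under each node."""
        n = self.n_leaves
        out = {i: self.ids[i] for i in range(n)}
        for i, (a, b, _) in enumerate(self.merges):
            out[n + i] = min(out[a], out[b])
        return out

    def leaf_order(self) -> list[str]:
        """Canonical left-to-right leaf order: at each internal node the
        child holding the lexicographically smaller minimal leaf id is
        drawn first."""
        n = self.n_leaves
        if n == 1:
            return list(self.ids)
        minleaf = self.node_min_leaf()
        children = {n + i: (a, b) for i, (a, b, _) in enumerate(self.merges)}
        order: list[str] = []
        stack = [n + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(self.ids[node])
            else:
                a, b = children[node]
                first, second = (a, b) if minleaf[a] <= minleaf[b] else (b, a)
                stack.append(second)
                stack.append(first)
        return order

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height deltas."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        for i, (_, _, h) in enumerate(self.merges):
            heights[n + i] = h
        minleaf = self.node_min_leaf()
        children = {n + i: (a, b) for i, (a, b, _) in enumerate(self.merges)}

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - heights[node]
            if node < n:
                return f"{self.ids[node]}:{bl:.10g}"
            a, b = children[node]
            if minleaf[a] > minleaf[b]:
                a, b = b, a
            inner = f"({render(a, heights[node])},{render(b, heights[node])})"
            return f"{inner}:{bl:.10g}"

        root = n + len(self.merges) - 1
        return render(root, heights[root]).rsplit(":", 1)[0] + ";"


@dataclass
class ClusterAssignment:
    """Flat grouping from a dendrogram cut; labels contiguous 1..k."""

    labels: dict[str, int]
    k: int

    def group_members(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {g: set() for g in range(1, self.k + 1)}
        for cid, g in self.labels.items():
            out[g].add(cid)
        return out

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.labels.items()), columns=["compound_id", "group"]
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ClusterAssignment":
        df = pd.read_csv(path, sep="\t")
        labels = dict(zip(df["compound_id"], df["group"].astype(int)))
        return cls(labels=labels, k=int(df["group"].max()))


def hcluster(D: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Agglomerate a symmetric distance matrix into a full merge tree.

    Deterministic: equal-distance candidate pairs are ordered by the
    sorted pair of their clusters' minimal member ids.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    ids = list(D.index)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 compounds to cluster")
    if list(D.columns) != ids:
        raise ValueError("distance matrix index and columns differ")
    V = D.to_numpy(dtype=float)
    if not np.allclose(V, V.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")

    # working distances; ward updates operate on squared distances
    work = V.copy() ** 2 if linkage == "ward" else V.copy()
    np.fill_diagonal(work, np.inf)
    node = list(range(n))  # active slot -> current node index
    size = [1] * n
    rep = [ids[i] for i in range(n)]  # minimal member id per slot
    active = [True] * n
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        best: tuple[float, str, str, int, int] | None = None
        act = [i for i in range(n) if active[i]]
        for ai in range(len(act)):
            for bi in range(ai + 1, len(act)):
                i, j = act[ai], act[bi]
                d = work[i, j]
                lo, hi = sorted((rep[i], rep[j]))
                cand = (d, lo, hi, i, j)
                if best is None or cand < best:
                    best = cand
        assert best is not None
        d, _, _, i, j = best
        height = float(np.sqrt(d)) if linkage == "ward" else float(d)
        a, b = node[i], node[j]
        if rep[j] < rep[i]:
            a, b = b, a
        merges.append((a, b, height))

        # Lance–Williams update into slot i
        ni, nj = size[i], size[j]
        for k in act:
            if k in (i, j):
                continue
            dik, djk = work[i, k], work[j, k]
            if linkage == "complete":
                dnew = max(dik, djk)
            elif linkage == "single":
                dnew = min(dik, djk)
            elif linkage == "average":
                dnew = (ni * dik + nj * djk) / (ni + nj)
            else:  # ward, squared distances
                nk = size[k]
                dnew = ((ni + nk) * dik + (nj + nk) * djk - nk * work[i, j]) / (
                    ni + nj + nk
                )
            work[i, k] = work[k, i] = dnew
        node[i] = n + step
        size[i] = ni + nj
        rep[i] = min(rep[i], rep[j])
        active[j] = False

    return Dendrogram(ids=ids, merges=merges, linkage=linkage)


def cut_tree(dend: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the dendrogram into exactly k groups.

    Applies the first n−k merges; group labels 1..k are assigned by order
    of each group's first appearance along the canonical leaf order, so
    "group 1" is always the leftmost branch.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    leaves_under = {i: [i] for i in range(n)}
    node_root = {i: i for i in range(n)}  # merge-node -> union-find root
    for i, (a, b, _) in enumerate(dend.merges[: n - k]):
        ra, rb = find(node_root[a]), find(node_root[b])
        parent[rb] = ra
        node_root[n + i] = ra

    member_to_root = {dend.ids[leaf]: find(leaf) for leaf in range(n)}
    order = dend.leaf_order()
    label_of_root: dict[int, int] = {}
    next_label = 1
    for cid in order:
        r = member_to_root[cid]
        if r not in label_of_root:
            label_of_root[r] = next_label
            next_label += 1
    labels = {cid: label_of_root[member_to_root[cid]] for cid in dend.ids}
    return ClusterAssignment(labels=labels, k=k)


def consistency_filter(
    D_wm: pd.DataFrame, k: int, min_cosize: int = 2
) -> set[str]:
    """Library-consistency screen over the western-drug distance matrix.

    Clusters the drugs alone, cuts at ``k``, and drops every drug sitting
    in a group smaller than ``min_cosize`` (by default: drugs that do not
    share a cluster-tree branch with at least one other drug).  Returns
    the retained drug id set.
    """
    dend = hcluster(D_wm, linkage="complete")
    assignment = cut_tree(dend, k)
    groups = assignment.group_members()
    retained: set[str] = set()
    for members in groups.values():
        if len(members) >= min_cosize:
            retained |= members
    return retained
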