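"""Single-linkage dendrograms over fingerprint distance matrices.

The mass-profile dendrogram is built by agglomerative single linkage: at
each step the two clusters at minimal distance merge, where the distance
between clusters is the minimum over their cross pairs.  Ties are broken
by the lexicographically smallest pair of cluster keys (a cluster's key is
its smallest member label), so the merge order — and every downstream
grouping — is fully reproducible.  The default input distance is
1 - CCI so the dendrogram and the CCI heat map live on one scale;
Bray-Curtis works equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrices import DistanceMatrix

__all__ = [
    "Dendrogram",
    "Grouping",
    "linkage_single",
    "linkage_average",
    "to_newick",
    "cut",
    "SingleLinkage",
]

_NEEDS_QUOTE = set(" ()[]{}':;,\t\n")


def quote_newick_label(label: str) -> str:
    if any(c in _NEEDS_QUOTE for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class Grouping:
    """Partition of strains into labelled groups.

    Group ids are canonicalised to the smallest member label so two
    partitions can be diffed textually.
    """

    assignment: dict[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        canonical: dict[str, str] = {}
        for gid in set(self.assignment.values()):
            members = [s for s, g in self.assignment.items() if g == gid]
            rep = min(members)
            for s in members:
                canonical[s] = rep
        self.assignment = canonical

    @property
    def groups(self) -> dict[str, frozenset]:
        out: dict[str, set] = {}
        for strain, gid in self.assignment.items():
            out.setdefault(gid, set()).add(strain)
        return {g: frozenset(v) for g, v in out.items()}

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    def as_labels(self, order: list[str]) -> list[str]:
        return [self.assignment[s] for s in order]

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.assignment.items())
        return pd.DataFrame(rows, columns=["strain_id", "group"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def same_partition(self, other: "Grouping") -> bool:
        return set(self.groups.values()) == set(other.groups.values())


@dataclass
class Dendrogram:
    """Strictly binary merge tree: scipy-style node ids (leaves ``0..n-1``,
    merge ``i`` creates node ``n+i``) with non-decreasing merge heights."""

    leaf_labels: list[str]
    merges: list[tuple[int, int, float]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("single-linkage merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else self.merges[node - n][2]

    def node_members(self) -> dict[int, frozenset]:
        n = self.n_leaves
        members: dict[int, frozenset] = {i: frozenset([self.leaf_labels[i]]) for i in range(n)}
        for i, (a, b, _) in enumerate(self.merges):
            members[n + i] = members[a] | members[b]
        return members

    def to_newick(self) -> str:
        n = self.n_leaves
        root = n + len(self.merges) - 1

        def render(node: int, parent_height: float) -> str:
            length = parent_height - self.node_height(node)
            if node < n:
                return f"{quote_newick_label(self.leaf_labels[node])}:{length:.10g}"
            a, b, h = self.merges[node - n]
            return f"({render(a, h)},{render(b, h)}):{length:.10g}"

        a, b, h = self.merges[-1]
        return f"({render(a, h)},{render(b, h)});"

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick")

    def cut(self, k: int) -> Grouping:
        """Partition into k groups by removing the k-1 highest merges.

        Equal heights at the boundary are resolved by merge order (the
        merges performed first stay)."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        node_of = list(range(n))  # union-find slot per dendrogram node
        node_of += [0] * len(self.merges)
        for i, (a, b, _) in enumerate(self.merges[: n - k]):
            ra, rb = find(node_of[a]), find(node_of[b])
            parent[rb] = ra
            node_of[n + i] = ra
        assignment = {self.leaf_labels[i]: str(find(i)) for i in range(n)}
        return Grouping(assignment, provenance=f"dendrogram cut k={k}")

    def cophenetic(self) -> DistanceMatrix:
        """Matrix of merge heights at which each leaf pair first co-clusters."""
        n = self.n_leaves
        members = {i: [i] for i in range(n)}
        D = np.zeros((n, n))
        for i, (a, b, h) in enumerate(self.merges):
            for x in members[a]:
                for y in members[b]:
                    D[x, y] = D[y, x] = h
            members[n + i] = members.pop(a) + members.pop(b)
        return DistanceMatrix(self.leaf_labels, D)


def _linkage(d: DistanceMatrix, method: str) -> Dendrogram:
    if np.any(np.isnan(d.values)):
        raise ValueError("distance matrix contains NaN")
    labels = list(d.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two items to cluster")
    D = d.values.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    keys = labels.copy()  # cluster key = smallest member label, per slot
    node_id = list(range(n))
    sizes = np.ones(n, dtype=int)
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        sub = np.where(np.outer(active, active), D, np.inf)
        h = sub.min()
        ties = np.argwhere(np.isclose(sub, h, rtol=0.0, atol=0.0))
        pairs = [(i, j) for i, j in ties if i < j]
        i, j = min(pairs, key=lambda p: tuple(sorted((keys[p[0]], keys[p[1]]))))
        first, second = (i, j) if keys[i] <= keys[j] else (j, i)
        merges.append((node_id[first], node_id[second], float(h)))
        if method == "single":
            newrow = np.minimum(D[i], D[j])
        else:  # average (UPGMA-style, size-weighted)
            newrow = (sizes[i] * D[i] + sizes[j] * D[j]) / (sizes[i] + sizes[j])
        D[i] = newrow
        D[:, i] = newrow
        D[i, i] = np.inf
        active[j] = False
        keys[i] = min(keys[i], keys[j])
        sizes[i] += sizes[j]
        node_id[i] = n + step
    return Dendrogram(labels, merges, provenance={"method": method})


def linkage_single(d: DistanceMatrix) -> Dendrogram:
    """Agglomerative single linkage with deterministic tie-breaking."""
    return _linkage(d, "single")


def linkage_average(d: DistanceMatrix) -> Dendrogram:
    """Average linkage, provided for robustness checks only."""
    return _linkage(d, "average")


def to_newick(tree) -> str:
    """Serialise a Dendrogram (or any object exposing ``to_newick``)."""
    return tree.to_newick()


def cut(t: Dendrogram, k: int) -> Grouping:
    return t.cut(k)


class SingleLinkage(BaseEstimator):
    """sklearn-style wrapper: fit a precomputed distance matrix, expose the
    dendrogram and a flat ``labels_`` cut."""

    def __init__(self, n_clusters: int = 4):
        self.n_clusters = n_clusters

    def fit(self, X, y=None, labels: list[str] | None = None) -> "SingleLinkage":
        if isinstance(X, DistanceMatrix):
            d = X
        else:
            X = np.asarray(X, float)
            if labels is None:
                labels = [str(i) for i in range(X.shape[0])]
            d = DistanceMatrix(labels, X)
        self.dendrogram_ = linkage_single(d)
        grouping = self.dendrogram_.cut(self.n_clusters)
        group_ids = sorted(set(grouping.assignment.values()))
        code = {g: i for i, g in enumerate(group_ids)}
        self.grouping_ = grouping
        self.labels_ = np.array([code[grouping.assignment[l]] for l in d.labels])
        return self

    def fit_predict(self, X, y=None, labels: list[str] | None = None) -> np.ndarray:
        return self.fit(X, labels=labels).labels_
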