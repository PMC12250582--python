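"""Hierarchical variable clustering under the homogeneity criterion.

Variables (here binarized 0/1 indicators, treated as quantitative after
centering and unit-scaling) are grouped so that each cluster is well
summarized by a synthetic variable — the cluster's first principal
component. The homogeneity of a cluster is the largest eigenvalue of its
correlation matrix, equal to the sum of squared correlations of the member
variables with the synthetic variable; a singleton has homogeneity 1.

Agglomeration starts from singletons and at each step merges the pair
(A, B) with the smallest aggregation cost

    d(A, B) = H(A) + H(B) - H(A ∪ B)  >=  0,

i.e. the loss in total homogeneity, with lexicographic tie-breaking on the
smallest member name. Cutting the merge history at K clusters yields the
K-cluster partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

_TIE_TOL = 1e-12


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(X.shape[1])])


def _check_variance(df: pd.DataFrame) -> None:
    sd = df.std(axis=0, ddof=0)
    zero = sorted(df.columns[sd.to_numpy() == 0.0].astype(str))
    if zero:
        raise ValueError(f"zero-variance variables cannot be clustered: {zero}")


def homogeneity(X) -> float:
    """Largest eigenvalue of the correlation matrix of the given columns."""
    df = _as_frame(X)
    if df.shape[1] == 0:
        raise ValueError("homogeneity requires at least one column")
    _check_variance(df)
    if df.shape[1] == 1:
        return 1.0
    corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    return float(np.linalg.eigvalsh(corr)[-1])


def _block_eigmax(R: np.ndarray, idx: list[int]) -> float:
    if len(idx) == 1:
        return 1.0
    return float(np.linalg.eigvalsh(R[np.ix_(idx, idx)])[-1])


@dataclass
class VariableClusterTree:
    """Agglomeration history: n-1 merges over the leaf variables."""

    leaves: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    total_homogeneity_path: list[float]   # after 0, 1, ..., n-1 merges

    def cut(self, k: int) -> dict[str, int]:
        """Partition into k clusters by replaying the first n-k merges.

        Cluster ids are canonical: ordered by size descending, ties by the
        lexicographically smallest member name.
        """
        n = len(self.leaves)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        parent = {name: name for name in self.leaves}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b, _ in self.merges[: n - k]:
            ra, rb = find(a[0]), find(b[0])
            parent[rb] = ra
        groups: dict[str, list[str]] = {}
        for name in self.leaves:
            groups.setdefault(find(name), []).append(name)
        ordered = sorted((sorted(m) for m in groups.values()),
                         key=lambda m: (-len(m), m[0]))
        return {name: cid for cid, members in enumerate(ordered)
                for name in members}

    def clusters(self, k: int) -> list[list[str]]:
        part = self.cut(k)
        out: dict[int, list[str]] = {}
        for name, cid in part.items():
            out.setdefault(cid, []).append(name)
        return [sorted(out[c]) for c in sorted(out)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "leaves": self.leaves,
            "merges": [{"a": list(a), "b": list(b), "height": h}
                       for a, b, h in self.merges],
            "total_homogeneity_path": self.total_homogeneity_path,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def cluster_variables(X) -> VariableClusterTree:
    """Agglomerative homogeneity clustering of the columns of X."""
    df = _as_frame(X)
    if df.shape[1] < 2:
        raise ValueError("need at least two variables to cluster")
    _check_variance(df)
    names = [str(c) for c in df.columns]
    order = np.argsort(names)                      # canonical column order
    names_sorted = [names[i] for i in order]
    R = np.corrcoef(df.to_numpy(dtype=float)[:, order], rowvar=False)

    clusters: dict[int, list[int]] = {i: [i] for i in range(len(names_sorted))}
    H: dict[int, float] = {i: 1.0 for i in clusters}
    cost: dict[tuple[int, int], tuple[float, float]] = {}

    def pair_cost(a: int, b: int) -> tuple[float, float]:
        h_union = _block_eigmax(R, clusters[a] + clusters[b])
        return H[a] + H[b] - h_union, h_union

    ids = sorted(clusters)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            cost[(a, b)] = pair_cost(a, b)

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    path = [float(len(names_sorted))]
    next_id = len(names_sorted)
    while len(clusters) > 1:
        d_min = min(d for d, _ in cost.values())
        candidates = [(k, v) for k, v in cost.items() if v[0] <= d_min + _TIE_TOL]

        def tie_key(item):
            (a, b), _ = item
            na = names_sorted[min(clusters[a])]
            nb = names_sorted[min(clusters[b])]
            return tuple(sorted((na, nb)))

        (a, b), (d, h_union) = min(candidates, key=tie_key)
        members_a = tuple(names_sorted[i] for i in sorted(clusters[a]))
        members_b = tuple(names_sorted[i] for i in sorted(clusters[b]))
        if members_a[0] > members_b[0]:
            members_a, members_b = members_b, members_a
        merges.append((members_a, members_b, float(d)))
        path.append(path[-1] - d)

        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        H[next_id] = h_union
        del H[a], H[b]
        cost = {k: v for k, v in cost.items() if a not in k and b not in k}
        for other in clusters:
            if other != next_id:
                key = (min(other, next_id), max(other, next_id))
                cost[key] = pair_cost(other, next_id)
        next_id += 1

    return VariableClusterTree(leaves=names_sorted, merges=merges,
                               total_homogeneity_path=path)


def top_variable_clusters(tree: VariableClusterTree, k: int = 3
                          ) -> list[list[str]]:
    """cut(k) clusters ordered by size descending (lexicographic ties)."""
    if k > len(tree.leaves):
        raise ValueError(f"k={k} exceeds the {len(tree.leaves)} leaves")
    return tree.clusters(k)


class VariableClusterer(TransformerMixin, ClusterMixin, BaseEstimator):
    """sklearn-style wrapper: cluster the *columns* of X.

    Analogous to feature agglomeration: ``fit`` builds the homogeneity
    merge tree and cuts it at ``n_clusters``; ``labels_`` holds one cluster
    id per input column, and ``transform`` returns the synthetic variable
    (first-principal-component score of the standardized member block) for
    each cluster.
    """

    def __init__(self, n_clusters: int = 3):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        df = _as_frame(X)
        if self.n_clusters < 1 or self.n_clusters > df.shape[1]:
            raise ValueError("n_clusters must be in [1, n_features]")
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        self.tree_ = cluster_variables(df)
        part = self.tree_.cut(self.n_clusters)
        self.labels_ = np.array([part[str(c)] for c in df.columns])
        self.clusters_ = self.tree_.clusters(self.n_clusters)

        Z = df.to_numpy(dtype=float)
        self.means_ = Z.mean(axis=0)
        self.scales_ = Z.std(axis=0, ddof=0)
        Z = (Z - self.means_) / self.scales_
        name_to_col = {str(c): i for i, c in enumerate(df.columns)}
        self._components = []
        for members in self.clusters_:
            idx = [name_to_col[m] for m in members]
            corr = np.corrcoef(Z[:, idx], rowvar=False) if len(idx) > 1 \
                else np.ones((1, 1))
            vals, vecs = np.linalg.eigh(corr)
            v = vecs[:, -1]
            if v.sum() < 0:
                v = -v
            self._components.append((idx, v))
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        df = _as_frame(X)
        Z = (df.to_numpy(dtype=float) - self.means_) / self.scales_
        return np.column_stack([Z[:, idx] @ v for idx, v in self._components])

    def top_clusters(self, k: int | None = None) -> list[list[str]]:
        check_is_fitted(self, "tree_")
        return top_variable_clusters(self.tree_, k or self.n_clusters)
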