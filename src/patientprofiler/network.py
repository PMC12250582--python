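"""OER-weighted phenotypic comorbidity networks.

The edge statistic is the observed-to-expected ratio for a code pair
(i, j): OER_ij = C_ij * N / (C_i * C_j), where C_i, C_j are the per-code
patient counts, C_ij the co-occurrence count and N the cohort size. OER > 1
means the pair co-occurs more often than expected under independence; the
analysis network keeps exactly those edges, and the "prominent" network
additionally thresholds at a per-cohort OER quantile (default the 90th
percentile of the OER > 1 edges, linear-interpolation quantile).

The five network metrics (diameter, degree, betweenness, average path
length, closeness) are computed on the unweighted simple graph: degree as
the raw neighbour count, betweenness unnormalized, closeness normalized to
(0, 1]. Community detection is fast-unfolding (Louvain) modularity
optimization; by default it sees the OER edge weights, matching how Gephi's
modularity routine treats weighted graphs, while the metrics stay
unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .cohorts import FeatureMatrix

DEFAULT_COMMUNITY_SEED = 20220901


def compute_oer_edges(matrix: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    """All-pairs OER table with columns feature_i, feature_j, c_ij, oer.

    Pairs are unordered (i < j by column order); features with zero
    prevalence must be removed beforehand.
    """
    data = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
    X = data.to_numpy(dtype=np.int64)
    n_patients = X.shape[0]
    counts = X.sum(axis=0)
    if (counts == 0).any():
        bad = [c for c, k in zip(data.columns, counts) if k == 0]
        raise ValueError(f"zero-prevalence features present: {bad}")
    co = X.T @ X
    iu, ju = np.triu_indices(X.shape[1], k=1)
    c_ij = co[iu, ju]
    oer = c_ij.astype(float) * n_patients / (counts[iu] * counts[ju])
    cols = np.asarray(data.columns, dtype=object)
    return pd.DataFrame({
        "feature_i": cols[iu], "feature_j": cols[ju],
        "c_i": counts[iu], "c_j": counts[ju], "c_ij": c_ij, "oer": oer,
    })


def build_network(edges: pd.DataFrame, *, mode: str = "analysis",
                  percentile: float = 0.90,
                  node_counts: pd.Series | None = None) -> nx.Graph:
    """Filter the OER edge table into a simple undirected graph.

    mode='analysis' keeps edges with OER > 1; mode='prominent' additionally
    keeps only edges at or above the ``percentile`` quantile of the
    OER > 1 edge weights. Isolated nodes are dropped. The realized
    threshold is stored in ``G.graph['oer_threshold']``.
    """
    if mode not in ("analysis", "prominent"):
        raise ValueError("mode must be 'analysis' or 'prominent'")
    positive = edges[edges["oer"] > 1.0]
    threshold = 1.0
    if mode == "prominent" and len(positive):
        threshold = float(np.quantile(positive["oer"].to_numpy(), percentile,
                                      method="linear"))
        positive = positive[positive["oer"] >= threshold]
    G = nx.Graph(mode=mode, oer_threshold=threshold)
    for row in positive.itertuples():
        G.add_edge(row.feature_i, row.feature_j, oer=float(row.oer),
                   weight=float(row.oer), c_ij=int(row.c_ij))
    if node_counts is not None:
        for node in G.nodes:
            G.nodes[node]["prevalence"] = int(node_counts.get(node, 0))
    if G.number_of_edges() == 0:
        import logging
        logging.getLogger(__name__).warning(
            "no edges survive the %s filter; network is empty", mode)
    return G


@dataclass
class NetworkMetrics:
    """Node-level and graph-level unweighted metrics."""

    degree: pd.Series
    betweenness: pd.Series        # unnormalized shortest-path pair counts
    closeness: pd.Series          # normalized to (0, 1]
    diameter: int | None
    avg_path_length: float | None
    node_path_length: pd.Series = field(repr=False, default=None)

    @property
    def avg_degree(self) -> float:
        return float(self.degree.mean())

    @property
    def avg_betweenness(self) -> float:
        return float(self.betweenness.mean())

    @property
    def avg_closeness(self) -> float:
        return float(self.closeness.mean())

    def summary(self) -> dict:
        return {
            "nodes": int(len(self.degree)),
            "diameter": self.diameter,
            "avg_degree": self.avg_degree,
            "avg_path_length": self.avg_path_length,
            "avg_betweenness": self.avg_betweenness,
            "avg_closeness": self.avg_closeness,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"degree": self.degree,
                             "betweenness": self.betweenness,
                             "closeness": self.closeness}).rename_axis("node")


def compute_metrics(G: nx.Graph) -> NetworkMetrics:
    """Unweighted metrics; diameter/path length on the largest component."""
    if G.number_of_nodes() == 0:
        raise ValueError("cannot compute metrics on an empty network")
    nodes = sorted(G.nodes)
    degree = pd.Series({n: d for n, d in G.degree()}, dtype=float)[nodes]
    betweenness = pd.Series(nx.betweenness_centrality(G, normalized=False,
                                                      weight=None))[nodes]
    closeness = pd.Series(nx.closeness_centrality(G))[nodes]
    if G.number_of_nodes() == 1:
        diameter: int | None = 0
        apl: float | None = None
        npl = pd.Series(np.nan, index=nodes)
    else:
        comp = max(nx.connected_components(G), key=len)
        H = G.subgraph(comp)
        if H.number_of_nodes() > 1:
            lengths = dict(nx.all_pairs_shortest_path_length(H))
            diameter = int(max(max(d.values()) for d in lengths.values()))
            per_node = {u: sum(d.values()) / (len(d) - 1)
                        for u, d in lengths.items()}
            apl = float(nx.average_shortest_path_length(H))
            npl = pd.Series(per_node).reindex(nodes)
        else:
            diameter, apl = 0, None
            npl = pd.Series(np.nan, index=nodes)
    return NetworkMetrics(degree=degree, betweenness=betweenness,
                          closeness=closeness, diameter=diameter,
                          avg_path_length=apl, node_path_length=npl)


def detect_communities(G: nx.Graph, *, resolution: float = 1.0,
                       seed: int = DEFAULT_COMMUNITY_SEED,
                       use_weights: bool = True
                       ) -> tuple[dict[str, int], float]:
    """Fast-unfolding (Louvain) modularity communities.

    Node order is canonicalized (sorted codes) before optimization so the
    result is deterministic for a fixed seed. Returns (node -> community id,
    modularity of the returned partition under the same weighting).
    """
    if G.number_of_nodes() == 0:
        raise ValueError("cannot detect communities on an empty network")
    H = nx.Graph()
    H.add_nodes_from(sorted(G.nodes))
    H.add_edges_from((u, v, d) for u, v, d in G.edges(data=True))
    weight = "weight" if use_weights else None
    comms = nx.community.louvain_communities(H, weight=weight,
                                             resolution=resolution, seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    partition = {node: cid for cid, members in enumerate(comms)
                 for node in members}
    modularity = float(nx.community.modularity(
        H, comms, weight=weight, resolution=resolution))
    return partition, modularity


def resolution_search(G: nx.Graph, *, min_communities: int = 3,
                      grid: np.ndarray | None = None,
                      seed: int = DEFAULT_COMMUNITY_SEED,
                      use_weights: bool = True) -> float:
    """Smallest resolution in [0.8, 1.6] yielding >= min_communities."""
    if grid is None:
        grid = np.round(np.arange(0.8, 1.61, 0.05), 2)
    for gamma in grid:
        partition, _ = detect_communities(G, resolution=float(gamma),
                                          seed=seed, use_weights=use_weights)
        if len(set(partition.values())) >= min_communities:
            return float(gamma)
    return float(grid[-1])


def top_clusters(partition: dict[str, int], k: int = 3
                 ) -> tuple[list[list[str]], pd.DataFrame]:
    """The k largest communities, size-descending.

    Ties broken by the lexicographically smallest member code. The
    distribution table reports each cluster's share of the top-k node
    universe (sums to 100% over the top k) and of all partitioned nodes.
    """
    groups = {}
    for node, cid in partition.items():
        groups.setdefault(cid, []).append(node)
    ordered = sorted((sorted(m) for m in groups.values()),
                     key=lambda m: (-len(m), m[0]))
    if len(ordered) < k:
        import logging
        logging.getLogger(__name__).warning(
            "only %d communities available (requested %d)", len(ordered), k)
    top = ordered[:k]
    total_all = sum(len(m) for m in ordered)
    total_top = sum(len(m) for m in top)
    dist = pd.DataFrame({
        "rank": np.arange(1, len(top) + 1),
        "size": [len(m) for m in top],
        "pct_of_top": [round(100.0 * len(m) / total_top, 2) for m in top],
        "pct_of_all": [round(100.0 * len(m) / total_all, 2) for m in top],
    })
    return top, dist


def compare_networks(metrics_a: NetworkMetrics, metrics_b: NetworkMetrics
                     ) -> pd.DataFrame:
    """Welch two-sample t-tests on node-level metric distributions.

    Path length is compared on per-node average shortest-path lengths and
    reported N/A (NaN) when either side is degenerate.
    """
    rows = []
    pairs = {
        "degree": (metrics_a.degree, metrics_b.degree),
        "betweenness": (metrics_a.betweenness, metrics_b.betweenness),
        "closeness": (metrics_a.closeness, metrics_b.closeness),
        "path_length": (metrics_a.node_path_length.dropna(),
                        metrics_b.node_path_length.dropna()),
    }
    for name, (a, b) in pairs.items():
        a, b = np.asarray(a, float), np.asarray(b, float)
        degenerate = (len(a) < 2 or len(b) < 2
                      or (np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0))
        if degenerate:
            rows.append({"metric": name, "t": np.nan, "pvalue": np.nan,
                         "note": "N/A"})
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            rows.append({"metric": name, "t": float(res.statistic),
                         "pvalue": float(res.pvalue), "note": ""})
    return pd.DataFrame(rows).set_index("metric")


def export_graph(G: nx.Graph, path: str | Path, *, fmt: str = "gexf",
                 metrics: NetworkMetrics | None = None,
                 partition: dict[str, int] | None = None,
                 viz: bool = False, viz_percentile: float = 0.50) -> Path:
    """Write a Gephi-compatible GEXF/GraphML file.

    Node attributes: prevalence, community, degree, betweenness, closeness;
    edge attribute: oer. With ``viz=True`` only edges strictly above the
    ``viz_percentile`` quantile of the edge weights are written — a
    visualization convenience that never feeds metrics or clustering.
    """
    if fmt not in ("gexf", "graphml"):
        raise ValueError("fmt must be 'gexf' or 'graphml'")
    H = G.copy()
    if viz and H.number_of_edges() > 0:
        w = np.array([d["oer"] for _, _, d in H.edges(data=True)])
        cut = float(np.quantile(w, viz_percentile, method="linear"))
        H.remove_edges_from([(u, v) for u, v, d in H.edges(data=True)
                             if d["oer"] <= cut])
        H.remove_nodes_from(list(nx.isolates(H)))
    if metrics is not None:
        for node in H.nodes:
            H.nodes[node]["degree"] = float(metrics.degree.get(node, 0))
            H.nodes[node]["betweenness"] = float(metrics.betweenness.get(node, 0))
            H.nodes[node]["closeness"] = float(metrics.closeness.get(node, 0))
    if partition is not None:
        for node in H.nodes:
            H.nodes[node]["community"] = int(partition.get(node, -1))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "gexf":
        nx.write_gexf(H, path)
    else:
        nx.write_graphml(H, path)
    return path


class ComorbidityNetworkClusterer(ClusterMixin, BaseEstimator):
    """Cluster binary features through an OER co-occurrence network.

    fit(X) computes all-pairs OER on the patients x features matrix, builds
    the filtered network and runs fast-unfolding community detection; the
    result labels *features* (columns), with -1 for features isolated out of
    the network.

    Parameters
    ----------
    edge_mode : 'analysis' (OER > 1) or 'prominent' (adds the percentile
        threshold).
    percentile : OER quantile for the prominent network.
    resolution : Louvain resolution gamma.
    use_weights : whether community detection sees OER edge weights.
    random_state : Louvain seed.
    """

    def __init__(self, edge_mode: str = "analysis", percentile: float = 0.90,
                 resolution: float = 1.0, use_weights: bool = True,
                 random_state: int = DEFAULT_COMMUNITY_SEED):
        self.edge_mode = edge_mode
        self.percentile = percentile
        self.resolution = resolution
        self.use_weights = use_weights
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, FeatureMatrix):
            data = X.data
        elif isinstance(X, pd.DataFrame):
            data = X
        else:
            X = np.asarray(X)
            data = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        self.feature_names_in_ = np.asarray(data.columns, dtype=object)
        self.n_features_in_ = data.shape[1]
        self.edges_ = compute_oer_edges(data)
        self.graph_ = build_network(self.edges_, mode=self.edge_mode,
                                    percentile=self.percentile,
                                    node_counts=data.sum(axis=0))
        self.threshold_ = self.graph_.graph["oer_threshold"]
        if self.graph_.number_of_nodes() > 0:
            self.partition_, self.modularity_ = detect_communities(
                self.graph_, resolution=self.resolution,
                seed=self.random_state, use_weights=self.use_weights)
            self.metrics_ = compute_metrics(self.graph_)
        else:
            self.partition_, self.modularity_ = {}, float("nan")
            self.metrics_ = None
        self.labels_ = np.array([self.partition_.get(c, -1)
                                 for c in data.columns])
        return self

    def top_clusters(self, k: int = 3) -> list[list[str]]:
        check_is_fitted(self, "partition_")
        return top_clusters(self.partition_, k=k)[0]
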