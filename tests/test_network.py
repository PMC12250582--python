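"""OER edges, network construction, metrics, communities, export."""

from __future__ import annotations

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from patientprofiler import (ComorbidityNetworkClusterer, build_network,
                             compare_networks, compute_metrics,
                             compute_oer_edges, detect_communities,
                             export_graph, top_clusters)
from patientprofiler.cohorts import FeatureMatrix
from patientprofiler.config import SimulationConfig, default_blocks
from patientprofiler.simulate import generate_cohort_events


def _edge_frame(oers: list[float]) -> pd.DataFrame:
    return pd.DataFrame({
        "feature_i": [f"a{i}" for i in range(len(oers))],
        "feature_j": [f"b{i}" for i in range(len(oers))],
        "c_i": 1, "c_j": 1, "c_ij": 1, "oer": oers,
    })


# --- OER formula -----------------------------------------------------------

def _matrix_from_counts(n, c_i, c_j, c_ij):
    a = [1] * c_i + [0] * (n - c_i)
    b = [1] * c_ij + [0] * (c_i - c_ij) + [1] * (c_j - c_ij)
    b += [0] * (n - len(b))
    return FeatureMatrix(pd.DataFrame({"A": a, "B": b}), "diagnosis")


@pytest.mark.parametrize("n,c_i,c_j,c_ij,expected", [
    (100, 10, 10, 1, 1.0),       # independence point of the formula
    (100, 10, 10, 0, 0.0),
    (200, 40, 50, 25, 2.5),
])
def test_oer_formula_fixtures(n, c_i, c_j, c_ij, expected):
    edges = compute_oer_edges(_matrix_from_counts(n, c_i, c_j, c_ij))
    assert edges["oer"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_oer_matches_brute_force_and_is_symmetric():
    rng = np.random.default_rng(42)
    for _ in range(5):
        X = pd.DataFrame(rng.random((60, 8)) < rng.uniform(0.2, 0.8, 8),
                         columns=list("abcdefgh")).astype(int)
        X = X.loc[:, X.sum() > 0]
        edges = compute_oer_edges(FeatureMatrix(X, "diagnosis"))
        seen = {}
        for row in edges.itertuples():
            seen[(row.feature_i, row.feature_j)] = row.oer
        n = len(X)
        for i, j in itertools.permutations(X.columns, 2):
            c_ij = int((X[i] & X[j]).sum())
            expected = c_ij * n / (X[i].sum() * X[j].sum())
            key = (i, j) if (i, j) in seen else (j, i)
            assert seen[key] == pytest.approx(expected, abs=1e-12)


def test_oer_rejects_zero_prevalence_features():
    X = pd.DataFrame({"A": [1, 0], "B": [0, 0]})
    with pytest.raises(ValueError, match="B"):
        compute_oer_edges(FeatureMatrix(X, "diagnosis"))


def test_cij_bounded_by_marginals(study):
    edges = compute_oer_edges(study["pooled"]["diagnosis"])
    assert (edges["c_ij"] <= np.minimum(edges["c_i"], edges["c_j"])).all()


# --- network construction --------------------------------------------------

def test_all_oer_below_one_gives_empty_network():
    G = build_network(_edge_frame([0.2, 0.9, 1.0]))
    assert G.number_of_nodes() == 0 and G.number_of_edges() == 0


def test_percentile_threshold_matches_quantile_rule():
    oers = np.round(np.arange(1.1, 2.01, 0.1), 10).tolist()
    G = build_network(_edge_frame(oers), mode="prominent", percentile=0.90)
    thr = float(np.quantile(oers, 0.90))     # linear-interpolation oracle
    expected_edges = sum(o >= thr for o in oers)
    assert G.number_of_edges() == expected_edges == 1
    assert G.graph["oer_threshold"] == pytest.approx(thr)


def test_raising_percentile_never_adds_edges():
    rng = np.random.default_rng(5)
    oers = (0.5 + 2 * rng.random(40)).tolist()
    previous = None
    for pct in (0.1, 0.5, 0.9, 0.99):
        G = build_network(_edge_frame(oers), mode="prominent", percentile=pct)
        edges = {tuple(sorted(e)) for e in G.edges}
        if previous is not None:
            assert edges <= previous
        previous = edges


def test_prominent_edges_concentrate_within_blocks(study):
    truth = study["truth"]
    m = study["pooled"]["diagnosis"]
    G = build_network(compute_oer_edges(m), mode="prominent", percentile=0.90)
    blocks = truth.diagnosis_blocks
    within = sum(blocks.get(u) == blocks.get(v) for u, v in G.edges)
    assert within / G.number_of_edges() >= 0.90


def test_null_model_shows_no_block_enrichment():
    """With multiplier 1 the prominent-network retention rate is the same
    for within-block and cross-block pairs (binomial tolerance)."""
    blocks = default_blocks(34, multiplier=1.0)
    cfg = SimulationConfig(n_patients=5000, seed=11, diagnosis_blocks=blocks,
                           procedure_blocks=blocks)
    _, _, truth = generate_cohort_events(cfg)
    X = truth.X_diagnosis
    X = X.loc[:, X.mean() >= 0.01]
    edges = compute_oer_edges(FeatureMatrix(X, "diagnosis"))
    G = build_network(edges, mode="prominent", percentile=0.90)
    bm = truth.diagnosis_blocks
    retained = {tuple(sorted(e)) for e in G.edges}
    within = edges[[bm.get(i) == bm.get(j)
                    for i, j in zip(edges.feature_i, edges.feature_j)]]
    cross = edges[[bm.get(i) != bm.get(j)
                   for i, j in zip(edges.feature_i, edges.feature_j)]]

    def rate(df):
        hits = sum(tuple(sorted((i, j))) in retained
                   for i, j in zip(df.feature_i, df.feature_j))
        return hits / len(df), len(df)

    rw, nw = rate(within)
    rc, nc = rate(cross)
    p = (rw * nw + rc * nc) / (nw + nc)
    tol = 4 * np.sqrt(p * (1 - p) * (1 / nw + 1 / nc))
    assert abs(rw - rc) <= tol


# --- metrics: closed forms and brute-force oracle --------------------------

def _bfs_lengths(adj, s):
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def _count_paths_through(adj, s, t, dist_s):
    """Enumerate all shortest s-t paths; return (#paths, per-node counts)."""
    target_len = dist_s[t]
    through: dict = {}
    total = 0
    stack = [(s, [s])]
    while stack:
        u, path = stack.pop()
        if u == t:
            total += 1
            for v in path[1:-1]:
                through[v] = through.get(v, 0) + 1
            continue
        for v in adj[u]:
            if v in dist_s and dist_s[v] == len(path) and dist_s[v] <= target_len:
                if dist_s[t] >= dist_s[v]:
                    stack.append((v, path + [v]))
    return total, through


def _brute_metrics(G):
    nodes = sorted(G.nodes)
    n = len(nodes)
    adj = {u: sorted(G.neighbors(u)) for u in nodes}
    degree = {u: len(adj[u]) for u in nodes}
    dist = {u: _bfs_lengths(adj, u) for u in nodes}
    betweenness = {u: 0.0 for u in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        total, through = _count_paths_through(adj, s, t, dist[s])
        for v, k in through.items():
            betweenness[v] += k / total
    closeness = {}
    for u in nodes:
        reach = len(dist[u]) - 1
        tot = sum(dist[u].values())
        closeness[u] = (reach / tot) * (reach / (n - 1)) if tot > 0 else 0.0
    return degree, betweenness, closeness


@pytest.mark.parametrize("seed", range(4))
def test_metrics_agree_with_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 13))
    G = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(0, 10_000)))
    G.remove_nodes_from(list(nx.isolates(G)))
    if G.number_of_nodes() == 0:
        pytest.skip("degenerate draw")
    m = compute_metrics(G)
    degree, betweenness, closeness = _brute_metrics(G)
    for u in G.nodes:
        assert m.degree[u] == degree[u]
        assert m.betweenness[u] == pytest.approx(betweenness[u], abs=1e-9)
        assert m.closeness[u] == pytest.approx(closeness[u], abs=1e-9)


def test_path_graph_closed_forms():
    G = nx.Graph([("a", "b"), ("b", "c")])
    m = compute_metrics(G)
    assert m.diameter == 2
    assert m.betweenness["b"] == 1.0 and m.betweenness["a"] == 0.0
    assert m.closeness["b"] == 1.0


def test_star_graph_center_betweenness():
    G = nx.star_graph(4)
    m = compute_metrics(G)
    assert m.betweenness[0] == 6.0        # C(4, 2) leaf pairs
    assert m.closeness[0] == 1.0


def test_triangle_closed_forms():
    m = compute_metrics(nx.complete_graph(3))
    assert m.avg_degree == 2.0
    assert m.avg_path_length == 1.0
    assert m.diameter == 1
    assert (m.betweenness == 0).all()


def test_singleton_network_degenerate_contract():
    G = nx.Graph()
    G.add_node("only")
    m = compute_metrics(G)
    assert m.diameter == 0 and m.avg_path_length is None


def test_metrics_use_largest_component():
    G = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
    m = compute_metrics(G)
    assert m.diameter == 2                # from the a-b-c component


# --- community detection ---------------------------------------------------

def _all_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield [[first]] + part


def test_two_cliques_match_exhaustive_modularity_oracle():
    G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    G.add_edge(0, 4)
    best = max(_all_partitions(list(G.nodes)),
               key=lambda p: nx.community.modularity(G, p))
    partition, modularity = detect_communities(G, use_weights=False)
    found = {}
    for node, cid in partition.items():
        found.setdefault(cid, set()).add(node)
    assert {frozenset(c) for c in found.values()} == \
        {frozenset(c) for c in best}
    assert modularity == pytest.approx(nx.community.modularity(G, best))


def test_complete_graph_is_one_community():
    partition, _ = detect_communities(nx.complete_graph(7), use_weights=False)
    assert len(set(partition.values())) == 1


def test_partition_beats_trivial_partitions(study):
    m = study["pooled"]["diagnosis"]
    G = build_network(compute_oer_edges(m))
    partition, modularity = detect_communities(G)
    comms: dict = {}
    for node, cid in partition.items():
        comms.setdefault(cid, set()).add(node)
    singletons = [{n} for n in G.nodes]
    whole = [set(G.nodes)]
    for trivial in (singletons, whole):
        assert modularity >= nx.community.modularity(
            G, trivial, weight="weight") - 1e-12


def test_detection_is_deterministic(study):
    m = study["pooled"]["diagnosis"]
    G = build_network(compute_oer_edges(m))
    p1, m1 = detect_communities(G, seed=123)
    p2, m2 = detect_communities(G, seed=123)
    assert p1 == p2 and m1 == m2


def test_block_recovery_by_network_method(study):
    from sklearn.metrics import adjusted_rand_score
    truth = study["truth"]
    m = study["pooled"]["diagnosis"]
    clu = ComorbidityNetworkClusterer().fit(m)
    blocks = truth.diagnosis_blocks
    common = [c for c in m.data.columns if c in blocks]
    ari = adjusted_rand_score([blocks[c] for c in common],
                              [clu.partition_.get(c, -1) for c in common])
    assert ari >= 0.9


# --- top clusters ----------------------------------------------------------

def test_top_cluster_distribution_arithmetic():
    partition = {}
    node = 0
    for size, cid in ((14, 0), (11, 1), (9, 2)):
        for _ in range(size):
            partition[f"n{node:02d}"] = cid
            node += 1
    top, dist = top_clusters(partition, k=3)
    assert [len(c) for c in top] == [14, 11, 9]
    assert dist["pct_of_top"].tolist() == [41.18, 32.35, 26.47]
    assert dist["pct_of_top"].sum() == pytest.approx(100.0)


def test_single_community_is_100_percent():
    _, dist = top_clusters({"a": 0, "b": 0}, k=3)
    assert dist["pct_of_top"].tolist() == [100.0]


def test_tie_break_is_lexicographic():
    partition = {"b": 0, "d": 0, "a": 1, "c": 1, "e": 2}
    top, _ = top_clusters(partition, k=3)
    assert top == [["a", "c"], ["b", "d"], ["e"]]


# --- cross-network comparison ----------------------------------------------

def test_identical_networks_compare_equal():
    G = nx.gnp_random_graph(12, 0.4, seed=3)
    m = compute_metrics(G)
    res = compare_networks(m, m)
    for metric in ("degree", "betweenness", "closeness"):
        assert res.loc[metric, "pvalue"] == pytest.approx(1.0)


def test_welch_t_statistic_matches_hand_formula():
    G1 = nx.path_graph(6)
    G2 = nx.star_graph(5)
    m1, m2 = compute_metrics(G1), compute_metrics(G2)
    res = compare_networks(m1, m2)
    a = m1.degree.to_numpy(float)
    b = m2.degree.to_numpy(float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
    assert res.loc["degree", "t"] == pytest.approx(t_hand, rel=1e-12)


def test_degenerate_metric_reported_na():
    m = compute_metrics(nx.complete_graph(5))   # all degrees equal
    res = compare_networks(m, m)
    assert res.loc["degree", "note"] == "N/A"
    assert np.isnan(res.loc["degree", "pvalue"])


# --- export ----------------------------------------------------------------

def test_gexf_round_trip_preserves_attributes(tmp_path):
    G = nx.complete_graph(3)
    G = nx.relabel_nodes(G, {0: "a", 1: "b", 2: "c"})
    for u, v in G.edges:
        G[u][v]["oer"] = 1.5
        G[u][v]["weight"] = 1.5
    for n in G.nodes:
        G.nodes[n]["prevalence"] = 10
    m = compute_metrics(G)
    partition, _ = detect_communities(G)
    path = export_graph(G, tmp_path / "tri.gexf", metrics=m,
                        partition=partition)
    H = nx.read_gexf(path)
    assert set(H.nodes) == {"a", "b", "c"}
    for n in H.nodes:
        assert H.nodes[n]["prevalence"] == 10
        assert "community" in H.nodes[n] and "betweenness" in H.nodes[n]
    assert H["a"]["b"]["oer"] == 1.5


def test_graphml_round_trip(tmp_path):
    G = nx.Graph([("a", "b", {"oer": 2.0, "weight": 2.0})])
    path = export_graph(G, tmp_path / "g.graphml", fmt="graphml")
    H = nx.read_graphml(path)
    assert H["a"]["b"]["oer"] == 2.0


def test_viz_thinning_keeps_half_the_edges(tmp_path):
    G = nx.Graph()
    for i, w in enumerate(np.round(np.arange(1.1, 2.01, 0.1), 10)):
        G.add_edge(f"u{i}", f"v{i}", oer=float(w), weight=float(w))
    path = export_graph(G, tmp_path / "viz.gexf", viz=True)
    H = nx.read_gexf(path)
    assert H.number_of_edges() == 5       # strictly above the median weight


def test_empty_network_exports_valid_document(tmp_path):
    path = export_graph(nx.Graph(), tmp_path / "empty.gexf")
    H = nx.read_gexf(path)
    assert H.number_of_nodes() == 0


# --- estimator surface -----------------------------------------------------

def test_estimator_api(study):
    from sklearn.base import clone
    m = study["pooled"]["diagnosis"]
    clu = ComorbidityNetworkClusterer(percentile=0.8)
    assert clone(clu).get_params()["percentile"] == 0.8
    clu.fit(m)
    assert clu.labels_.shape == (m.data.shape[1],)
    assert clu.threshold_ >= 1.0
    assert len(clu.top_clusters(3)) == 3


# --- hypothesis properties -------------------------------------------------

from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays


@settings(max_examples=30, deadline=None, derandomize=True)
@given(arrays(np.int8, (12, 4), elements=st.integers(0, 1)))
def test_oer_formula_holds_on_arbitrary_binary_matrices(X):
    X = pd.DataFrame(X, columns=list("wxyz"))
    X = X.loc[:, X.sum() > 0]
    if X.shape[1] < 2:
        return
    edges = compute_oer_edges(FeatureMatrix(X, "diagnosis"))
    n = len(X)
    for row in edges.itertuples():
        a, b = X[row.feature_i], X[row.feature_j]
        assert row.c_ij == int((a & b).sum())
        assert row.oer == pytest.approx(row.c_ij * n / (a.sum() * b.sum()),
                                        abs=1e-12)
        assert row.c_ij <= min(a.sum(), b.sum())


def test_resolution_search_reaches_min_communities(study):
    from patientprofiler.network import resolution_search
    m = study["pooled"]["diagnosis"]
    G = build_network(compute_oer_edges(m))
    gamma = resolution_search(G, min_communities=3)
    partition, _ = detect_communities(G, resolution=gamma)
    assert 0.8 <= gamma <= 1.6
    assert len(set(partition.values())) >= 3
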