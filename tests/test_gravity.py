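"""Spatial graphs, node metrics, edge covariates and gravity-model fits."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conunit.gravity import (
    GravityHypothesis,
    aicc_from_loglik,
    build_graph,
    extract_edge_covariates,
    fit_gravity,
    node_metrics,
    predict_flow,
    rank_models_aicc,
)
from conunit.raster import NODATA, Raster
from conunit.synth import default_gravity_truth, simulate_gravity_flows


def _nodes(coords, **attrs):
    df = pd.DataFrame(coords, columns=["x", "y"])
    df.insert(0, "node_id", [f"n{i}" for i in range(len(df))])
    for k, v in attrs.items():
        df[k] = v
    return df


def _toy_graph(n_nodes, seed, span=50000.0):
    rng = np.random.default_rng(seed)
    nodes = _nodes(rng.uniform(0, span, size=(n_nodes, 2)),
                   hli=rng.normal(size=n_nodes))
    g = build_graph(nodes, "saturated")
    g.edges["cti"] = rng.normal(size=g.n_edges)
    return g


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def test_delaunay_triangle_and_saturated_counts():
    nodes = _nodes([(0, 0), (1000, 0), (500, 800)])
    assert build_graph(nodes, "delaunay").n_edges == 3
    n = 9
    rng = np.random.default_rng(0)
    sat = build_graph(_nodes(rng.uniform(0, 1e4, (n, 2))), "saturated")
    assert sat.n_edges == n * (n - 1) // 2


def test_prune_removes_exactly_long_edges():
    nodes = _nodes([(0, 0), (30000, 0), (100000, 0), (0, 20000)])
    full = build_graph(nodes, "saturated")
    pruned = build_graph(nodes, "saturated", prune_km=50)
    assert (pruned.edges["length_m"] <= 50000).all()
    dropped = full.n_edges - pruned.n_edges
    assert dropped == (full.edges["length_m"] > 50000).sum()


def test_duplicate_coordinates_jittered():
    nodes = _nodes([(0, 0), (0, 0), (1000, 1000)])
    g = build_graph(nodes, "delaunay")
    xy = g.nodes[["x", "y"]].to_numpy()
    assert len(np.unique(xy, axis=0)) == 3
    assert np.hypot(*(xy[0] - xy[1])) < 1.0


def test_collinear_points_fall_back_to_chain():
    nodes = _nodes([(0, 0), (1000, 0), (2000, 0), (3000, 0)])
    g = build_graph(nodes, "delaunay")
    assert g.n_edges == 3  # nearest-neighbour chain
    assert (g.edges["length_m"] == 1000).all()


# ---------------------------------------------------------------------------
# Node metrics
# ---------------------------------------------------------------------------

def _betweenness_bruteforce(edges, n):
    """Exhaustive shortest-path enumeration on an unweighted graph."""
    adj = {i: set() for i in range(n)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)

    def all_shortest_paths(s, t):
        # BFS layering then DFS enumeration
        from collections import deque
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        if t not in dist:
            return []
        paths = []

        def walk(u, path):
            if u == t:
                paths.append(path)
                return
            for v in adj[u]:
                if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                    walk(v, path + [v])

        walk(s, [s])
        return [p for p in paths if len(p) == dist[t] + 1]

    btw = dict.fromkeys(range(n), 0.0)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for node in range(n):
            if node in (s, t):
                continue
            through = sum(1 for p in paths if node in p)
            btw[node] += through / len(paths)
    return btw


def _graph_from_edges(edges, n):
    rng = np.random.default_rng(0)
    nodes = _nodes(rng.uniform(0, 1000, size=(n, 2)))
    ids = nodes["node_id"].tolist()
    rows = [dict(i=ids[a], j=ids[b],
                 length_m=float(np.hypot(nodes.x[a] - nodes.x[b],
                                         nodes.y[a] - nodes.y[b])) or 1.0)
            for a, b in edges]
    from conunit.gravity import SpatialGraph
    return SpatialGraph(nodes, pd.DataFrame(rows, columns=["i", "j", "length_m"]))


def test_betweenness_path_and_star_closed_forms():
    path = _graph_from_edges([(0, 1), (1, 2)], 3)
    m = node_metrics(path).set_index("node_id")
    assert m.loc["n1", "betweenness"] == pytest.approx(1.0)
    assert m.loc["n0", "betweenness"] == 0.0

    star = _graph_from_edges([(0, i) for i in range(1, 5)], 5)
    m = node_metrics(star).set_index("node_id")
    assert m.loc["n0", "betweenness"] == pytest.approx(6.0)  # L(L-1)/2
    assert m.loc["n0", "degree"] == 4


def test_betweenness_matches_bruteforce_on_random_graphs():
    rng = np.random.default_rng(21)
    for _ in range(100):
        n = int(rng.integers(3, 8))
        possible = list(itertools.combinations(range(n), 2))
        k = int(rng.integers(1, len(possible) + 1))
        idx = rng.choice(len(possible), size=k, replace=False)
        edges = [possible[i] for i in idx]
        g = _graph_from_edges(edges, n)
        got = node_metrics(g).set_index("node_id")["betweenness"]
        want = _betweenness_bruteforce(edges, n)
        for node, val in want.items():
            assert got[f"n{node}"] == pytest.approx(val, abs=1e-9)


def test_alpha_centrality_edgeless_graph_is_exogenous():
    g = _graph_from_edges([], 4)
    m = node_metrics(g)
    np.testing.assert_allclose(m["alpha_centrality"], 1.0)
    assert (m["degree"] == 0).all()


# ---------------------------------------------------------------------------
# Edge covariates
# ---------------------------------------------------------------------------

def test_constant_raster_gives_constant_medians():
    rast = Raster(np.full((40, 40), 7.5), 0.0, 0.0, 100.0)
    nodes = _nodes([(500, 500), (3500, 500), (2000, 3500)])
    g = build_graph(nodes, "saturated")
    g = extract_edge_covariates(g, {"c": rast})
    np.testing.assert_allclose(g.edges["c"], 7.5)


def test_edge_medians_correlate_across_widths():
    """On a smooth gradient the per-edge medians are nearly width-invariant
    (r > 0.85 between widths), so the native 30 m width suffices."""
    n = 120
    xs = np.arange(n) * 30.0
    grad = np.add.outer(xs[::-1] * 0.3, xs) / 1000.0
    rng = np.random.default_rng(3)
    grad += rng.normal(size=grad.shape) * 0.05
    rast = Raster(grad, 0.0, 0.0, 30.0)
    nodes = _nodes(rng.uniform(600, n * 30 - 600, size=(12, 2)))
    g = build_graph(nodes, "saturated")
    medians = {}
    for w in (30, 90, 150, 270, 510):
        medians[w] = extract_edge_covariates(g, {"c": rast}, width_m=w).edges["c"]
    widths = list(medians)
    for a, b in itertools.combinations(widths, 2):
        assert np.corrcoef(medians[a], medians[b])[0, 1] > 0.85


def test_nodata_edge_warns_and_sets_missing(caplog):
    vals = np.full((10, 10), NODATA)
    rast = Raster(vals, 0.0, 0.0, 100.0)
    nodes = _nodes([(150, 150), (850, 850)])
    g = build_graph(nodes, "saturated")
    g = extract_edge_covariates(g, {"c": rast})
    assert np.isnan(g.edges["c"]).all()


def test_edge_outside_extent_errors():
    rast = Raster(np.zeros((5, 5)), 0.0, 0.0, 100.0)
    nodes = _nodes([(100, 100), (2000, 2000)])
    g = build_graph(nodes, "saturated")
    with pytest.raises(ValueError, match="outside raster"):
        extract_edge_covariates(g, {"c": rast})


# ---------------------------------------------------------------------------
# AICc and fitting
# ---------------------------------------------------------------------------

def test_aicc_closed_form_and_limit():
    assert aicc_from_loglik(-50, 3, 100) == pytest.approx(106.25)
    assert -2 * -50 + 2 * 3 == 106  # AIC for the same fit
    big_n = 10**6
    assert aicc_from_loglik(-50, 5, big_n) - 110 < 0.01
    with pytest.raises(ValueError):
        aicc_from_loglik(-50, 5, 6)


def test_zero_noise_fit_recovers_truth_exactly():
    truth = default_gravity_truth()
    hyp = GravityHypothesis("tm", at_site=["hli"], between_site=["cti"])
    g = _toy_graph(12, 0)
    flows = simulate_gravity_flows(g, truth, 0.0, 0.0, seed=1)
    fit = fit_gravity(flows, g, hyp, mode="ML")
    for term, want in [("intercept", truth["intercept"]),
                       ("ln_dist", truth["ln_dist"]),
                       ("ln_hli_site", truth["ln_hli_site"]),
                       ("ln_cti", truth["ln_cti"])]:
        assert fit.coefficient(term) == pytest.approx(want, abs=1e-8)
    assert fit.smearing == pytest.approx(1.0, abs=1e-9)


def test_fit_rejects_bad_flows():
    g = _toy_graph(8, 1)
    hyp = GravityHypothesis("null")
    with pytest.raises(ValueError, match="flows"):
        fit_gravity(np.full(g.n_edges, 1.5), g, hyp)
    with pytest.raises(ValueError, match="one flow per edge"):
        fit_gravity(np.array([0.5]), g, hyp)


def test_missing_covariate_errors():
    g = _toy_graph(8, 2)
    hyp = GravityHypothesis("h", between_site=["absent"])
    with pytest.raises(ValueError, match="absent"):
        fit_gravity(np.full(g.n_edges, 0.5), g, hyp)


def test_rank_models_identical_hypotheses_tie():
    g = _toy_graph(15, 3)
    truth = default_gravity_truth()
    flows = simulate_gravity_flows(g, truth, 0.1, 0.15, seed=4)
    h1 = GravityHypothesis("a", at_site=["hli"], between_site=["cti"])
    h2 = GravityHypothesis("b", at_site=["hli"], between_site=["cti"])
    table = rank_models_aicc(flows, g, [h1, h2])
    assert table["aicc"].iloc[0] == pytest.approx(table["aicc"].iloc[1])
    assert np.allclose(table["delta_aicc"], 0.0)
    with pytest.raises(ValueError, match="duplicate"):
        rank_models_aicc(flows, g, [h1, h1])


def test_predict_flow_cutoff_and_pruning():
    truth = default_gravity_truth()
    hyp = GravityHypothesis("tm", at_site=["hli"], between_site=["cti"])
    g = _toy_graph(20, 5, span=30000.0)
    flows = simulate_gravity_flows(g, truth, 0.05, 0.1, seed=6)
    fit = fit_gravity(flows, g, hyp, mode="REML")

    rng = np.random.default_rng(9)
    target_nodes = g.nodes.copy()
    target = build_graph(target_nodes, "saturated", prune_km=15)
    target.edges["cti"] = rng.normal(size=target.n_edges)
    tab = predict_flow(fit, target, cutoff=0.85)
    assert (tab.table["length_m"] <= 15000).all()
    assert (tab.table["flagged"] == (tab.table["flow"] >= 0.85)).all()
    assert (tab.table["flow"] <= 1.0).all()
    # cutoff on flow corresponds to predicted Nei's D of 1 - cutoff
    assert np.allclose(1.0 - tab.table["flow"],
                       1.0 - tab.table["flow"].to_numpy())


def test_prediction_with_smearing_disabled_is_plain_exponential():
    truth = default_gravity_truth()
    hyp = GravityHypothesis("tm", at_site=["hli"], between_site=["cti"])
    g = _toy_graph(10, 7)
    flows = simulate_gravity_flows(g, truth, 0.0, 0.0, seed=8)
    fit = fit_gravity(flows, g, hyp, mode="ML")
    tab = predict_flow(fit, g, include_smearing=False)
    np.testing.assert_allclose(tab.table["flow"], flows, rtol=1e-8)
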