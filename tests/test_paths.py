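"""Pathway statistics: direct/shortest path definitions, the Dijkstra
implementation against exhaustive enumeration and networkx, and the
permutation comparison wrapper."""

import itertools

import networkx as nx
import numpy as np
import pytest

from rfnet._shortest import dijkstra, edge_lengths
from rfnet.errors import DomainError
from rfnet.network import EstimatorConfig
from rfnet.paths import compare_pathways, direct_pathways, shortest_pathways
from tests.conftest import make_network


def _net(entries, p, labels=None):
    W = np.zeros((p, p))
    for (i, j), w in entries.items():
        W[i, j] = W[j, i] = w
    return make_network(W, labels=labels)


def _brute_force(W, src, dst):
    """Shortest simple path by exhaustive enumeration (oracle)."""
    p = W.shape[0]
    L = edge_lengths(W)
    best = np.inf
    nodes = [v for v in range(p) if v not in (src, dst)]
    for r in range(len(nodes) + 1):
        for mid in itertools.permutations(nodes, r):
            path = (src, *mid, dst)
            length = sum(L[a, b] for a, b in zip(path, path[1:]))
            best = min(best, length)
    return best


def test_direct_pathways_signed_sum():
    labels = ["rf1", "rf2", "rf3", "GD"]
    net = _net({(0, 3): -0.2, (1, 3): -0.3, (2, 3): 0.1}, 4, labels)
    res = direct_pathways(net)
    assert res.dp == pytest.approx(-0.4)
    # invariant to RF-RF edges
    net2 = _net({(0, 3): -0.2, (1, 3): -0.3, (2, 3): 0.1, (0, 1): 0.5}, 4, labels)
    assert direct_pathways(net2).dp == pytest.approx(-0.4)


def test_isolated_target_gives_zero_dp():
    net = _net({(0, 1): 0.4}, 4, ["a", "b", "c", "GD"])
    res = direct_pathways(net)
    assert res.dp == 0.0 and np.abs(res.direct_weight).max() == 0.0


def test_missing_target_errors():
    with pytest.raises(DomainError):
        direct_pathways(_net({}, 3, ["a", "b", "c"]))


def test_single_edge_direct_classification():
    net = _net({(0, 2): 0.5}, 3, ["rf1", "rf2", "GD"])
    res = shortest_pathways(net)
    i = res.rf_labels.index("rf1")
    assert res.path_length[i] == pytest.approx(2.0)
    assert res.classification[i] == "direct"
    assert res.classification[res.rf_labels.index("rf2")] == "none"


def test_indirect_route_beats_weak_direct_edge():
    net = _net({(0, 1): 0.5, (1, 2): 0.5, (0, 2): 0.1}, 3, ["rf1", "rf2", "GD"])
    res = shortest_pathways(net)
    i = res.rf_labels.index("rf1")
    assert res.path_length[i] == pytest.approx(4.0)
    assert res.classification[i] == "indirect"
    assert res.path_nodes[i] == ["rf1", "rf2", "GD"]


def test_dijkstra_equals_enumeration_and_networkx(rng):
    for _ in range(100):
        p = int(rng.integers(3, 7))
        W = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < 0.5:
                    W[i, j] = W[j, i] = rng.uniform(0.05, 0.6) * rng.choice([-1, 1])
        L = edge_lengths(W)
        dist, _ = dijkstra(L, p - 1)
        G = nx.from_numpy_array(np.where(np.isfinite(L), L, 0.0))
        for v in range(p - 1):
            assert dist[v] == pytest.approx(_brute_force(W, v, p - 1), abs=1e-10)
            try:
                nx_len = nx.dijkstra_path_length(G, v, p - 1)
            except nx.NetworkXNoPath:
                nx_len = np.inf
            if not np.isfinite(dist[v]):
                assert not np.isfinite(nx_len)
            else:
                assert dist[v] == pytest.approx(nx_len, abs=1e-10)


def test_adding_edge_never_lengthens_paths(rng):
    p = 6
    W = np.zeros((p, p))
    for i in range(p - 1):
        W[i, i + 1] = W[i + 1, i] = 0.3
    d0, _ = dijkstra(edge_lengths(W), 0)
    W2 = W.copy()
    W2[0, 4] = W2[4, 0] = 0.2
    d1, _ = dijkstra(edge_lengths(W2), 0)
    assert (d1 <= d0 + 1e-12).all()


def test_star_network_sp_closed_form():
    labels = [f"rf{i}" for i in range(10)] + ["GD"]
    entries = {(i, 10): -0.25 for i in range(10)}
    res = shortest_pathways(_net(entries, 11, labels))
    assert res.sp == pytest.approx(10 / 0.25)
    assert all(c == "direct" for c in res.classification)


def test_classification_partition():
    net = _net({(0, 1): 0.5, (1, 4): 0.4, (2, 4): 0.6}, 5, ["a", "b", "c", "d", "GD"])
    res = shortest_pathways(net)
    counts = {c: res.classification.count(c) for c in ("direct", "indirect", "none")}
    assert sum(counts.values()) == 4


def test_unreachable_penalty_recorded():
    net = _net({(0, 3): 0.5}, 4, ["a", "b", "c", "GD"])
    res = shortest_pathways(net)
    assert res.unreachable_penalty == pytest.approx(2 * 2.0)
    assert res.sp == pytest.approx(2.0 + 4.0 + 4.0)


def test_compare_identical_inputs_p_one(rng):
    from rfnet.cohort import partial_to_correlation

    W = np.zeros((4, 4))
    W[0, 3] = W[3, 0] = -0.3
    W[1, 2] = W[2, 1] = 0.3
    R = partial_to_correlation(W)
    X = rng.standard_normal((150, 4)) @ np.linalg.cholesky(R).T
    import pandas as pd

    frame = pd.DataFrame(X, columns=["a", "b", "c", "GD"])
    res = compare_pathways(frame, frame.copy(), K=25, seed=2, config=EstimatorConfig(n_lambda=25))
    assert res.observed["delta_dp"] == 0.0
    assert res.observed["delta_sp"] == 0.0
    assert res.p_values["delta_dp"] == 1.0
    assert res.p_values["delta_sp"] == 1.0
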