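import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ranksig import (
    ABSTAIN,
    ConfigError,
    DataError,
    build_graph,
    classify_majority,
    detect_communities,
    evaluate,
    evaluate_loo,
    label_clusters,
    threshold_edges,
)


def dist_frame(n, rng=None, fill=None):
    idx = pd.Index([f"s{i:02d}" for i in range(n)], name="sample_id")
    if fill is not None:
        arr = np.full((n, n), float(fill))
    else:
        half = rng.uniform(0, 1, size=(n, n))
        arr = (half + half.T) / 2
    np.fill_diagonal(arr, 0.0)
    return pd.DataFrame(arr, index=idx, columns=idx)


class TestThresholdEdges:
    def test_ceil_rule(self, rng):
        assert len(threshold_edges(dist_frame(5, rng), 20)) == 2  # ceil(.2*10)

    def test_full_percentage_gives_complete_graph(self, rng):
        assert len(threshold_edges(dist_frame(6, rng), 100)) == 15

    def test_all_ties_resolved_by_pair_id(self):
        kept = threshold_edges(dist_frame(5, fill=0.5), 10)
        assert kept == [("s00", "s01")]  # exactly ceil(1), first pair id

    def test_kept_never_exceed_excluded(self, rng):
        d = dist_frame(12, rng)
        kept = set(threshold_edges(d, 30))
        excluded = {tuple(sorted(p)) for p in
                    itertools.combinations(d.index, 2)} - kept
        assert max(d.at[a, b] for a, b in kept) <= min(d.at[a, b] for a, b in excluded)

    def test_fewer_than_two_samples(self, rng):
        with pytest.raises(DataError):
            threshold_edges(dist_frame(1, rng), 10)

    @pytest.mark.parametrize("N", [0, -5, 101])
    def test_invalid_percentage(self, rng, N):
        with pytest.raises(ConfigError):
            threshold_edges(dist_frame(4, rng), N)

    def test_edge_count_law_sweep(self, rng):
        for n in range(3, 16):
            d = dist_frame(n, rng)
            P = n * (n - 1) // 2
            for N in (1, 10, 20, 50, 100):
                assert len(threshold_edges(d, N)) == math.ceil(N / 100 * P)


class TestBuildGraph:
    def test_isolated_nodes_kept(self, rng):
        d = dist_frame(3, rng)
        g = build_graph(d, [("s00", "s01")])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 1
        assert g.degree["s02"] == 0

    def test_weight_contract(self):
        d = dist_frame(2, fill=0.3)
        g = build_graph(d, [("s00", "s01")])
        assert g.edges["s00", "s01"]["weight"] == pytest.approx(0.7)

    def test_no_kept_pairs(self, rng):
        assert build_graph(dist_frame(4, rng), []).number_of_edges() == 0


def two_cliques_graph():
    g = nx.Graph()
    left, right = [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]
    for group in (left, right):
        for u, v in itertools.combinations(group, 2):
            g.add_edge(u, v, distance=0.1, weight=0.9)
    g.add_edge("a0", "b0", distance=0.9, weight=0.1)
    return g, left, right


class TestDetectCommunities:
    def test_two_cliques_recovered_and_optimal(self):
        g, left, right = two_cliques_graph()
        part = detect_communities(g)
        groups = {}
        for node, cid in part.items():
            groups.setdefault(cid, set()).add(node)
        assert sorted(map(sorted, groups.values())) == [sorted(left), sorted(right)]
        # the clique split is the modularity-optimal 2-partition (exhaustive)
        best = max(
            (frozenset(c) for r in range(1, 5)
             for c in itertools.combinations(g.nodes, r)),
            key=lambda c: nx.community.modularity(
                g, [set(c), set(g.nodes) - set(c)], weight="weight"))
        assert {frozenset(left), frozenset(right)} == {best, frozenset(g.nodes) - best}

    def test_edgeless_graph_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y", "z"])
        part = detect_communities(g)
        assert sorted(part.values()) == [0, 1, 2]

    def test_single_clique(self):
        g = nx.Graph()
        for u, v in itertools.combinations("abcd", 2):
            g.add_edge(u, v, distance=0.1, weight=0.9)
        assert set(detect_communities(g).values()) == {0}

    def test_empty_graph_is_error(self):
        with pytest.raises(DataError):
            detect_communities(nx.Graph())


class TestLabelClusters:
    def test_majority_of_anchors(self):
        part = {"s1": 0, "s2": 0, "s3": 0}
        anchors = pd.Series({"s1": "control", "s2": "control", "s3": "unknown"})
        assert label_clusters(part, anchors) == {0: "control"}

    def test_anchor_tie_is_unknown(self):
        part = {"s1": 0, "s2": 0, "s3": 1}
        anchors = pd.Series({"s1": "control", "s2": "affected", "s3": "control"})
        assert label_clusters(part, anchors)[0] == "unknown"

    def test_anchor_free_community_unknown(self):
        part = {"s1": 0, "s2": 1}
        anchors = pd.Series({"s1": "affected"})
        assert label_clusters(part, anchors) == {0: "affected", 1: "unknown"}

    def test_no_anchors_anywhere_is_error(self):
        with pytest.raises(DataError):
            label_clusters({"s1": 0}, pd.Series({"s1": "unknown"}))


def star_graph(center, neighbors):
    """center connected to (label, distance) neighbors."""
    g = nx.Graph()
    g.add_node(center)
    labels = {}
    for i, (label, d) in enumerate(neighbors):
        node = f"n{i}"
        g.add_edge(center, node, distance=d, weight=1 - d)
        labels[node] = label
    return g, pd.Series(labels)


class TestClassifyMajority:
    def test_unweighted_majority(self):
        g, known = star_graph("t", [("affected", 0.1), ("affected", 0.2),
                                    ("control", 0.05)])
        out = classify_majority(g, known, targets=["t"])
        assert out.loc["t", "predicted"] == "affected"
        assert out.loc["t", "vote_affected"] == 2

    def test_tie_abstains(self):
        g, known = star_graph("t", [("affected", 0.1), ("control", 0.4)])
        assert classify_majority(g, known, targets=["t"]).loc["t", "predicted"] == ABSTAIN

    def test_weighted_vote_overrides_count(self):
        g, known = star_graph("t", [("affected", 0.1), ("control", 0.4)])
        out = classify_majority(g, known, weighted=True, targets=["t"])
        assert out.loc["t", "predicted"] == "affected"
        assert out.loc["t", "vote_affected"] == pytest.approx(10.0)
        assert out.loc["t", "vote_control"] == pytest.approx(2.5)

    def test_isolated_node_abstains(self):
        g, known = star_graph("t", [("affected", 0.1)])
        g.add_node("lonely")
        assert classify_majority(g, known,
                                 targets=["lonely"]).loc["lonely", "predicted"] == ABSTAIN

    def test_unweighted_invariant_weighted_not(self):
        neighbors = [("affected", 0.1), ("control", 0.2), ("control", 0.25)]
        g1, known = star_graph("t", neighbors)
        # monotone rescale d -> d^2 changes weighted tallies, not counts
        g2, _ = star_graph("t", [(l, d * d) for l, d in neighbors])
        u1 = classify_majority(g1, known, targets=["t"])
        u2 = classify_majority(g2, known, targets=["t"])
        pd.testing.assert_frame_equal(u1, u2)
        w1 = classify_majority(g1, known, weighted=True, targets=["t"])
        w2 = classify_majority(g2, known, weighted=True, targets=["t"])
        assert w1.loc["t", "predicted"] == w2.loc["t", "predicted"]
        assert not np.isclose(w1.loc["t", "vote_control"], w2.loc["t", "vote_control"])

    def test_zero_distance_neighbor_is_safe(self):
        g, known = star_graph("t", [("affected", 0.0), ("control", 0.5)])
        out = classify_majority(g, known, weighted=True, targets=["t"])
        assert out.loc["t", "predicted"] == "affected"
        assert np.isfinite(out.loc["t", "vote_affected"])


class TestEvaluate:
    def test_abstain_counts_as_error(self):
        truth = pd.Series({f"s{i}": ("affected" if i < 5 else "control")
                           for i in range(10)})
        pred = truth.copy()
        pred["s0"] = "control"   # one wrong
        pred["s9"] = ABSTAIN     # one abstain
        m = evaluate(pred, truth)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["n_abstain"] == 1

    def test_all_correct(self):
        truth = pd.Series({"a": "affected", "b": "control"})
        m = evaluate(truth.copy(), truth)
        assert m["sensitivity"] == m["specificity"] == 1.0

    def test_all_affected_called_control(self):
        truth = pd.Series({"a": "affected", "b": "affected", "c": "control"})
        pred = pd.Series("control", index=truth.index)
        m = evaluate(pred, truth)
        assert m["sensitivity"] == 0.0 and m["specificity"] == 1.0

    def test_empty_evaluation_is_error(self):
        with pytest.raises(DataError):
            evaluate(pd.Series(dtype=object), pd.Series({"a": "unknown"}))


def test_perfect_phenotype_separation_gives_loo_accuracy_one():
    """When the kept edges never cross phenotypes, every connected node is
    classified correctly by its neighbors' true labels."""
    g, left, right = two_cliques_graph()
    g.remove_edge("a0", "b0")
    truth = pd.Series({**{n: "control" for n in left},
                       **{n: "affected" for n in right}})
    _, metrics = evaluate_loo(g, truth)
    assert metrics["accuracy"] == 1.0 and metrics["n_abstain"] == 0
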