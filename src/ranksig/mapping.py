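"""Similarity-map construction, community partitioning, cluster labeling,
neighbor majority-vote diagnosis and its evaluation.

The map keeps only the smallest N% of the n(n-1)/2 pairwise distances as
edges of an undirected graph over the samples; phenotype groups then emerge
as graph communities (found by greedy modularity maximization on
weight = 1 - distance). A sample is diagnosed by a majority count over the
phenotypes of its immediate neighbors — optionally weighting each vote by
the inverse of the neighbor distance — with an exact tie or an isolated
node recorded as an abstention, which the evaluation scores as an error.
"""

from __future__ import annotations

import math

import networkx as nx
import pandas as pd

from .errors import ConfigError, DataError
from .io import canonical_pair

#: value a diagnosis takes when no strict majority exists
ABSTAIN = "abstain"

#: floor inside inverse-distance vote weights, guards division by zero
WEIGHT_EPS = 1e-12


def threshold_edges(distances: pd.DataFrame, N: float) -> list[tuple[str, str]]:
    """Keep the K = ceil(N/100 * P) smallest of the P pairwise distances.

    Ties straddling the cutoff are resolved by lexicographic pair id so that
    exactly K pairs are kept. Requires at least two samples and 0 < N <= 100.
    """
    if not 0 < N <= 100:
        raise ConfigError(f"N must be a percentage in (0, 100]; got {N}")
    samples = list(distances.index)
    n = len(samples)
    if n < 2:
        raise DataError("need at least two samples to build a map")
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = canonical_pair(samples[i], samples[j])
            pairs.append((float(distances.iat[i, j]), a, b))
    pairs.sort()
    K = math.ceil(N / 100.0 * len(pairs))
    return [(a, b) for _, a, b in pairs[:K]]


def threshold_edges_absolute(distances: pd.DataFrame, max_distance: float
                             ) -> list[tuple[str, str]]:
    """Alternative filter: keep every pair with distance <= *max_distance*."""
    samples = list(distances.index)
    if len(samples) < 2:
        raise DataError("need at least two samples to build a map")
    kept = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            if float(distances.iat[i, j]) <= max_distance:
                kept.append(canonical_pair(samples[i], samples[j]))
    return sorted(kept)


def build_graph(distances: pd.DataFrame, kept_pairs) -> nx.Graph:
    """Undirected sample map: every sample a node (isolated ones included),
    kept pairs as edges carrying ``distance`` and ``weight = 1 - distance``."""
    graph = nx.Graph()
    graph.add_nodes_from(distances.index)
    for a, b in kept_pairs:
        d = float(distances.at[a, b])
        graph.add_edge(a, b, distance=d, weight=1.0 - d)
    return graph


def detect_communities(graph: nx.Graph) -> dict[str, int]:
    """Partition the map by greedy modularity maximization on edge weights.

    Every node is assigned exactly one community; isolated nodes become
    singletons. Community ids are assigned deterministically, ordered by
    each community's smallest member node label.
    """
    if graph.number_of_nodes() == 0:
        raise DataError("cannot partition an empty map")
    if graph.number_of_edges() == 0:
        groups = [{node} for node in graph.nodes]
    else:
        groups = [set(c) for c in
                  nx.community.greedy_modularity_communities(graph, weight="weight")]
    groups.sort(key=lambda c: min(str(x) for x in c))
    return {node: cid for cid, group in enumerate(groups) for node in group}


def label_clusters(partition: dict[str, int], anchors: pd.Series) -> dict[int, str]:
    """Give each community the majority phenotype of its anchor members.

    *anchors* maps sample id to phenotype; ``unknown`` entries do not vote.
    An anchor tie, or a community without anchors, yields ``unknown``.
    Having no informative anchor anywhere is a hard error.
    """
    known = anchors[anchors.isin(["control", "affected"])]
    if known.empty:
        raise DataError("cluster labeling requires at least one labeled anchor sample")
    out: dict[int, str] = {}
    for cid in sorted(set(partition.values())):
        members = [s for s, c in partition.items() if c == cid]
        votes = known.reindex(members).dropna().value_counts()
        if votes.empty or (len(votes) == 2 and votes.iloc[0] == votes.iloc[1]):
            out[cid] = "unknown"
        else:
            out[cid] = votes.idxmax()
    return out


def classify_majority(graph: nx.Graph, known: pd.Series, *, weighted: bool = False,
                      targets=None) -> pd.DataFrame:
    """Diagnose samples by the majority phenotype of their graph neighbors.

    For each target node the control/affected labels of its immediate
    neighbors are tallied — one vote per neighbor, or ``1/max(d, eps)``
    votes when *weighted* — and the strict majority wins. An exact tie or
    the absence of any labeled neighbor yields :data:`ABSTAIN`. A node's own
    label never votes for itself, so passing the full truth table performs
    the leave-one-out protocol.

    Returns a DataFrame indexed by sample id with columns ``predicted``,
    ``vote_control`` and ``vote_affected``.
    """
    if targets is None:
        targets = list(graph.nodes)
    rows = []
    for node in targets:
        tally = {"control": 0.0, "affected": 0.0}
        for nbr in graph.neighbors(node):
            label = known.get(nbr, "unknown")
            if label not in tally:
                continue
            if weighted:
                tally[label] += 1.0 / max(graph[node][nbr]["distance"], WEIGHT_EPS)
            else:
                tally[label] += 1.0
        if tally["control"] > tally["affected"]:
            call = "control"
        elif tally["affected"] > tally["control"]:
            call = "affected"
        else:
            call = ABSTAIN
        rows.append((node, call, tally["control"], tally["affected"]))
    frame = pd.DataFrame(rows, columns=["sample_id", "predicted", "vote_control",
                                        "vote_affected"])
    return frame.set_index("sample_id")


def evaluate(predicted: pd.Series, truth: pd.Series) -> dict[str, float]:
    """Accuracy / sensitivity / specificity with abstention scored as error.

    Only samples whose truth is control or affected are evaluated;
    sensitivity is the fraction of affected samples called affected, and
    specificity the fraction of control samples called control.
    """
    known = truth[truth.isin(["control", "affected"])]
    evaluated = known.index.intersection(predicted.index)
    if len(evaluated) == 0:
        raise DataError("no sample with known phenotype to evaluate")
    pred = predicted.reindex(evaluated)
    true = known.reindex(evaluated)
    correct = pred == true
    affected = true == "affected"
    control = true == "control"
    return {
        "accuracy": float(correct.mean()),
        "sensitivity": float(correct[affected].mean()) if affected.any() else float("nan"),
        "specificity": float(correct[control].mean()) if control.any() else float("nan"),
        "n_evaluated": int(len(evaluated)),
        "n_abstain": int((pred == ABSTAIN).sum()),
    }


def evaluate_loo(graph: nx.Graph, truth: pd.Series, *, weighted: bool = False
                 ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Leave-one-out evaluation on a labeled map.

    Each node is classified from its neighbors' true labels (its own label
    is hidden — a node is never its own neighbor) and scored against truth.
    """
    known = truth[truth.isin(["control", "affected"])]
    diagnosis = classify_majority(graph, known, weighted=weighted,
                                  targets=[s for s in graph.nodes if s in known.index])
    return diagnosis, evaluate(diagnosis["predicted"], truth)
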