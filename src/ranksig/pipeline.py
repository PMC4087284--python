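"""End-to-end pipeline: files in, artifacts + metrics out.

Runs the whole chain — missing-value filter, virtual control, differential
transform, feature screen, signature extraction, distance matrix, edge
thresholding, map construction, community detection, cluster labeling,
majority-vote diagnosis, evaluation — and writes every intermediate as a
plain-text artifact. Used by the command-line interface; importable
directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io, mapping, preprocess, similarity
from .errors import ConfigError
from .signature import cohort_signatures

log = logging.getLogger("ranksig")


@dataclass
class PipelineConfig:
    matrix_path: str
    labels_path: str
    out_dir: str
    n1: int = 25
    n2: int = 25
    alpha: float = 0.1
    N: float = 10.0
    weighted: bool = False
    inclusive_alpha: bool = True
    feature_selection: bool = True
    absolute_threshold: float | None = None  # overrides the N% quantile filter
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ConfigError(f"n1 and n2 must be >= 1; got n1={self.n1}, n2={self.n2}")
        if not 0 < self.alpha <= 1:
            raise ConfigError(f"alpha must be in (0, 1]; got {self.alpha}")
        if not 0 < self.N <= 100:
            raise ConfigError(f"N must be in (0, 100]; got {self.N}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the metrics dict it also writes."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = io.read_matrix(config.matrix_path)
    labels = io.align_labels(io.read_labels(config.labels_path), matrix.columns)
    log.info("loaded %d probes x %d samples; labels: %s", *matrix.shape,
             labels.value_counts().to_dict())

    complete = preprocess.drop_incomplete_probes(matrix)
    log.info("missing-value filter: %d of %d probes retained",
             complete.shape[0], matrix.shape[0])

    diff = preprocess.differential_transform(complete,
                                             preprocess.virtual_control(complete))
    if config.feature_selection:
        report = preprocess.select_features(diff, labels, config.alpha,
                                            inclusive=config.inclusive_alpha)
        selected = diff.loc[report.index[report["selected"]]]
    else:
        report = pd.DataFrame({"U": float("nan"), "p": float("nan"), "selected": True},
                              index=diff.index)
        selected = diff
    report.rename_axis("probe_id").to_csv(out / "feature_report.tsv", sep="\t")
    log.info("feature screen (alpha=%g): %d of %d probes selected",
             config.alpha, selected.shape[0], diff.shape[0])
    if selected.shape[0] < config.n1 + config.n2:
        raise ConfigError(
            f"{selected.shape[0]} selected probes cannot carry an "
            f"n1={config.n1} + n2={config.n2} signature")

    rankings, signatures = cohort_signatures(selected, config.n1, config.n2)
    with open(out / "signatures.json", "w") as fh:
        json.dump({s: {"top": list(sig.top), "bottom": list(sig.bottom)}
                   for s, sig in signatures.items()}, fh, indent=1)
    log.info("extracted %d signatures of size %d+%d",
             len(signatures), config.n1, config.n2)

    dist, sim = similarity.distance_matrix(selected, config.n1, config.n2)
    dist.to_csv(out / "distance_matrix.tsv", sep="\t", float_format="%.10g")

    if config.absolute_threshold is not None:
        kept = mapping.threshold_edges_absolute(dist, config.absolute_threshold)
        log.info("absolute threshold %g: %d edges kept", config.absolute_threshold,
                 len(kept))
    else:
        kept = mapping.threshold_edges(dist, config.N)
        log.info("smallest %g%% of distances: %d edges kept", config.N, len(kept))
    io.write_edge_list(dist, kept, out / "edge_list.tsv")

    graph = mapping.build_graph(dist, kept)
    communities = mapping.detect_communities(graph)
    n_comm = len(set(communities.values()))
    log.info("community detection: %d communities over %d nodes",
             n_comm, graph.number_of_nodes())

    known = labels[labels.isin(["control", "affected"])]
    community_labels = {}
    metrics: dict = {"n_samples": int(matrix.shape[1]),
                     "n_probes": int(matrix.shape[0]),
                     "n_complete_probes": int(complete.shape[0]),
                     "n_selected_probes": int(selected.shape[0]),
                     "n_edges": len(kept),
                     "n_communities": n_comm}

    diagnosis = None
    if not known.empty:
        community_labels = mapping.label_clusters(communities, labels)
        diagnosis, loo = mapping.evaluate_loo(graph, labels, weighted=config.weighted)
        metrics.update(loo)
        log.info("leave-one-out majority vote: accuracy=%.3f sensitivity=%.3f "
                 "specificity=%.3f (%d abstained)", loo["accuracy"],
                 loo["sensitivity"], loo["specificity"], loo["n_abstain"])
        unknown_targets = [s for s in graph.nodes if s not in known.index]
        if unknown_targets:
            extra = mapping.classify_majority(graph, labels, weighted=config.weighted,
                                              targets=unknown_targets)
            diagnosis = pd.concat([diagnosis, extra])

    if diagnosis is not None:
        table = diagnosis.copy()
        table["true"] = labels.reindex(table.index)
        table.rename_axis("sample_id").to_csv(out / "diagnosis.tsv", sep="\t")

    predicted = diagnosis["predicted"] if diagnosis is not None else None
    io.export_graph(graph, labels, out / "map.graphml",
                    predicted=predicted, communities=communities)
    metrics["community_labels"] = {str(k): v for k, v in community_labels.items()}
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1, sort_keys=True)
    return metrics
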