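"""Readers and writers for the package's plain-text interchange formats.

Expression matrices are tab-separated text, one probe per row and one sample
per column, with a header row of sample identifiers and the probe identifier
in the first column. Intensities are linear-scale positive values; the
tokens ``NA`` and the empty string mark missing cells. Missing cells are
represented in memory as ``NaN`` in a float :class:`pandas.DataFrame`
(probes x samples) — the NaN pattern *is* the missing-value mask.

Label tables are two-column TSV files mapping sample id to one of the
phenotype vocabulary values ``control`` / ``affected`` / ``unknown`` and are
held as a :class:`pandas.Series` indexed by sample id.

Distances between samples are exported as an edge list (TSV) and the final
sample map as GraphML, loadable by standard graph viewers.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

import networkx as nx
import pandas as pd

from .errors import DataError

#: closed phenotype vocabulary for label tables
PHENOTYPES = ("control", "affected", "unknown")

#: tokens interpreted as a missing cell in expression matrices
MISSING_TOKENS = ("NA", "")


def _check_unique(values: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise DataError(f"duplicate {kind} ID {v!r}")
        seen.add(v)


def read_matrix(path) -> pd.DataFrame:
    """Read a probes-x-samples expression matrix from TSV.

    Returns a float DataFrame whose index holds probe ids and whose columns
    hold sample ids, in file order. Missing tokens become NaN. Duplicate
    probe or sample ids and non-numeric cells are hard errors.
    """
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise DataError(f"{path}: expression matrix needs a header row and at least one probe row")
    sample_ids = [str(s) for s in raw.iloc[0, 1:]]
    probe_ids = [str(p) for p in raw.iloc[1:, 0]]
    _check_unique(sample_ids, "sample")
    _check_unique(probe_ids, "probe")
    cells = raw.iloc[1:, 1:].copy()
    cells = cells.apply(lambda col: col.str.strip())
    missing = cells.isin(MISSING_TOKENS)
    numeric = cells.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~missing
    if bad.to_numpy().any():
        i, j = next(zip(*bad.to_numpy().nonzero()))
        raise DataError(
            f"{path}: non-numeric cell {cells.iat[i, j]!r} at probe "
            f"{probe_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    numeric.index = pd.Index(probe_ids, name="probe_id")
    numeric.columns = pd.Index(sample_ids, name="sample_id")
    return numeric.astype(float)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write an expression matrix as TSV, NaN cells as ``NA`` (round-trips)."""
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_labels(path) -> pd.Series:
    """Read a two-column TSV (sample_id, phenotype) label table.

    Phenotypes outside the closed vocabulary and duplicate sample ids are
    hard errors. A header row ``sample_id<TAB>phenotype`` is permitted.
    """
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if raw.shape[1] != 2:
        raise DataError(f"{path}: label table must have exactly two columns")
    rows = raw.values.tolist()
    if rows and rows[0][0] in ("sample_id", "sample") and rows[0][1] in ("phenotype", "label"):
        rows = rows[1:]
    labels: dict[str, str] = {}
    for sample, pheno in rows:
        if sample in labels:
            raise DataError(f"duplicate sample ID {sample!r} in label table")
        if pheno not in PHENOTYPES:
            raise DataError(
                f"unknown phenotype {pheno!r} for sample {sample!r}; "
                f"accepted values: {', '.join(PHENOTYPES)}"
            )
        labels[sample] = pheno
    out = pd.Series(labels, name="phenotype", dtype=object)
    out.index.name = "sample_id"
    return out


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("phenotype").rename_axis("sample_id").to_csv(path, sep="\t")


def align_labels(labels: pd.Series, sample_ids: Iterable[str]) -> pd.Series:
    """Join a label table onto a sample set; absent samples become unknown."""
    idx = pd.Index(list(sample_ids), name="sample_id")
    return labels.reindex(idx).fillna("unknown").rename("phenotype")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered sample pair lexicographically."""
    return (a, b) if a <= b else (b, a)


def write_edge_list(distances: pd.DataFrame, kept_pairs, path) -> None:
    """Write kept pairs as TSV (sample_a, sample_b, distance, similarity).

    Each unordered pair is written once with sample_a < sample_b; similarity
    is ``1 - 2*distance`` (the inverse of the distance map d = (1-s)/2).
    """
    rows = []
    for a, b in kept_pairs:
        if a == b:
            raise DataError(f"self-pair ({a!r}, {b!r}) in kept edge set")
        a, b = canonical_pair(a, b)
        d = float(distances.at[a, b])
        rows.append((a, b, d, 1.0 - 2.0 * d))
    rows.sort()
    frame = pd.DataFrame(rows, columns=["sample_a", "sample_b", "distance", "similarity"])
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edge_list(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_a": str, "sample_b": str})
    expected = ["sample_a", "sample_b", "distance", "similarity"]
    if list(frame.columns) != expected:
        raise DataError(f"{path}: edge list columns must be {expected}")
    return frame


def export_graph(graph: nx.Graph, labels: pd.Series, path, *,
                 predicted: pd.Series | None = None,
                 communities: dict | None = None) -> None:
    """Export a sample map as GraphML.

    Nodes carry ``sample_id`` and ``phenotype`` attributes (plus ``predicted``
    and ``community`` when supplied); edges carry ``distance`` and
    ``weight = 1 - distance``.
    """
    out = nx.Graph()
    for node in graph.nodes:
        attrs = {"sample_id": str(node), "phenotype": str(labels.get(node, "unknown"))}
        if predicted is not None and node in predicted.index:
            attrs["predicted"] = str(predicted[node])
        if communities is not None and node in communities:
            attrs["community"] = int(communities[node])
        out.add_node(node, **attrs)
    for a, b, data in graph.edges(data=True):
        d = float(data["distance"])
        if not math.isfinite(d):
            raise DataError(f"non-finite distance on edge ({a!r}, {b!r})")
        out.add_edge(a, b, distance=d, weight=1.0 - d)
    nx.write_graphml(out, path)
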