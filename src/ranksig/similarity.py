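"""Enrichment-score similarity between rank signatures and the all-to-all
distance matrix.

The enrichment score (ES) is the unweighted Kolmogorov-Smirnov-style
running-sum statistic: walking a ranked list of G probes, a probe inside the
query set of size m adds 1/m, a probe outside subtracts 1/(G-m); the ES is
the running-sum excursion of maximum absolute magnitude, signed. ES = +1
when the whole set sits at the head of the list, -1 when it sits at the
tail.

A signature has two parts, so its directional score against another sample
is the mean of two ES values: the top part scored on the other sample's
descending ranking and the bottom part on the *reversed* (ascending)
ranking, so that concordant under-expression also contributes positively.
The symmetric similarity of a pair is the mean of the two directional
scores, and distance is the affine map d = (1 - s) / 2 in [0, 1].
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .signature import Signature, cohort_signatures

__all__ = [
    "enrichment_score",
    "directional_es",
    "pairwise_similarity",
    "distance_matrix",
    "similarity_to_distance",
]


def similarity_to_distance(s):
    """Affine order-reversing map sending s=1 -> d=0 and s=-1 -> d=1."""
    return (1.0 - s) / 2.0


def _es_from_positions(pos: np.ndarray, m: int, G: int) -> float:
    """ES from the sorted 0-based hit positions of an m-set in a G-list.

    The running sum is piecewise linear and attains its maximum immediately
    after a hit and its minimum immediately before a hit (or at the ends,
    where it is 0), so only those 2m candidate values need inspection. On a
    magnitude tie between the positive and negative excursions the positive
    value is returned. Integer arithmetic on the common denominator m*(G-m)
    keeps every candidate value exact, so magnitude ties are decided
    correctly.
    """
    i = np.arange(1, m + 1, dtype=np.int64)
    misses_before = pos.astype(np.int64) + 1 - i  # misses strictly before each hit
    after = i * (G - m) - misses_before * m
    before = (i - 1) * (G - m) - misses_before * m
    hi = max(int(after.max()), 0)
    lo = min(int(before.min()), 0)
    return (hi if hi >= -lo else lo) / (m * (G - m))


def enrichment_score(ranking: Sequence[str], gene_set) -> float:
    """Unweighted running-sum ES of *gene_set* against *ranking*.

    Requires 0 < |gene_set| < len(ranking) and gene_set ⊆ ranking.
    """
    G = len(ranking)
    gene_set = set(gene_set)
    m = len(gene_set)
    if m == 0 or m >= G:
        raise DataError(f"gene set size must satisfy 0 < m < G; got m={m}, G={G}")
    pos = np.sort([i for i, g in enumerate(ranking) if g in gene_set])
    if pos.size != m:
        missing = gene_set - set(ranking)
        raise DataError(f"gene set members absent from ranking: {sorted(missing)[:5]}")
    return _es_from_positions(pos, m, G)


def directional_es(sig: Signature, ranking: Sequence[str]) -> float:
    """Score signature *sig* (of sample A) against sample B's ranking.

    Mean of the top-part ES on the descending ranking and the bottom-part ES
    on the reversed ranking.
    """
    es_top = enrichment_score(ranking, sig.top)
    es_bottom = enrichment_score(list(ranking)[::-1], sig.bottom)
    return (es_top + es_bottom) / 2.0


def pairwise_similarity(sig_a: Signature, ranking_a: Sequence[str],
                        sig_b: Signature, ranking_b: Sequence[str]) -> float:
    """Symmetric similarity in [-1, 1]: mean of the two directional scores."""
    return (directional_es(sig_a, ranking_b) + directional_es(sig_b, ranking_a)) / 2.0


def _positions(ranking: list[str], probe_index: dict[str, int]) -> np.ndarray:
    """Map a ranking to an array pos[probe_int_id] = 0-based rank position."""
    pos = np.empty(len(ranking), dtype=np.int64)
    for p, probe in enumerate(ranking):
        pos[probe_index[probe]] = p
    return pos


def distance_matrix(matrix: pd.DataFrame, n1: int, n2: int
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-to-all signature distances over a (selected-probe) matrix.

    Every sample shares the probe universe of *matrix* and the signature
    sizes (n1, n2). Returns ``(distances, similarities)`` as square
    DataFrames; distances have an exactly zero diagonal and are symmetric by
    construction.
    """
    samples = list(matrix.columns)
    rankings, signatures = cohort_signatures(matrix, n1, n2)
    G = matrix.shape[0]
    probe_index = {p: i for i, p in enumerate(matrix.index)}
    pos = {s: _positions(rankings[s], probe_index) for s in samples}
    top = {s: np.array([probe_index[p] for p in signatures[s].top]) for s in samples}
    bot = {s: np.array([probe_index[p] for p in signatures[s].bottom]) for s in samples}

    def one_way(a: str, b: str) -> float:
        # A's top on B's descending ranking; A's bottom on B's ascending one
        es_t = _es_from_positions(np.sort(pos[b][top[a]]), n1, G)
        es_b = _es_from_positions(np.sort(G - 1 - pos[b][bot[a]]), n2, G)
        return (es_t + es_b) / 2.0

    n = len(samples)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = (one_way(samples[i], samples[j]) + one_way(samples[j], samples[i])) / 2.0
            sim[i, j] = sim[j, i] = s
    dist = similarity_to_distance(sim)
    np.fill_diagonal(dist, 0.0)
    idx = pd.Index(samples, name="sample_id")
    return (pd.DataFrame(dist, index=idx, columns=idx),
            pd.DataFrame(sim, index=idx, columns=idx))
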