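"""Per-sample rank signatures.

A sample's signature is the *identity* of its n1 most-expressed and n2
least-expressed probes after the differential transform — a fingerprint of
which species deviate most from the cohort norm, in which direction. Only
the within-sample ordering of values enters, which is what makes the method
robust to calibration errors, batch effects and lab-to-lab protocol
differences: any strictly increasing rescaling of a profile yields the same
signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError


@dataclass(frozen=True)
class Signature:
    """Ordered top-n1 / bottom-n2 probe id lists for one sample."""

    sample_id: str
    top: tuple[str, ...]
    bottom: tuple[str, ...]

    def __post_init__(self):
        if set(self.top) & set(self.bottom):
            raise ConfigError(f"signature of {self.sample_id!r}: top and bottom overlap")


def rank_profile(values: pd.Series) -> list[str]:
    """Rank one profile's probes from highest to lowest value.

    Ties are broken by ascending probe id, so the ordering is deterministic
    and platform-independent. Values must be finite.
    """
    if len(values) == 0:
        raise DataError("cannot rank an empty profile")
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise DataError("profile contains non-finite values")
    # stable sort over lexicographically ordered probes == tie-break by probe id
    by_probe = values.sort_index()
    order = np.argsort(-by_probe.to_numpy(dtype=float), kind="stable")
    return [by_probe.index[i] for i in order]


def extract_signature(sample_id: str, ranking: list[str], n1: int, n2: int) -> Signature:
    """Take the first n1 and last n2 probe ids of a ranking."""
    G = len(ranking)
    if n1 < 1 or n2 < 1:
        raise ConfigError(f"signature sizes must be >= 1; got n1={n1}, n2={n2}")
    if n1 + n2 > G:
        raise ConfigError(
            f"signature does not fit: n1={n1} + n2={n2} exceeds the {G} ranked probes"
        )
    return Signature(sample_id, tuple(ranking[:n1]), tuple(ranking[G - n2:]))


def cohort_signatures(matrix: pd.DataFrame, n1: int, n2: int
                      ) -> tuple[dict[str, list[str]], dict[str, Signature]]:
    """Rank every sample of a (selected-probe) differential matrix and
    extract its signature. Returns ``(rankings, signatures)`` keyed by
    sample id."""
    rankings: dict[str, list[str]] = {}
    signatures: dict[str, Signature] = {}
    for sample in matrix.columns:
        ranking = rank_profile(matrix[sample])
        rankings[sample] = ranking
        signatures[sample] = extract_signature(sample, ranking, n1, n2)
    return rankings, signatures
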