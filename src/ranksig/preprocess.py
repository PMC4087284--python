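"""Preprocessing: missing-value filter, virtual-control differential
transform, and the nonstringent Mann-Whitney feature screen.

The differential transform divides every sample's profile, probe-wise, by a
*virtual control* — the arithmetic mean of all input profiles — so that
values express deviation from the cohort norm. Because the divisor is a
positive per-probe constant, within-probe sample ordering (and hence every
rank statistic downstream) is unchanged by the transform.

Feature selection keeps probes whose differential values differ between the
control and affected groups by a two-sided Mann-Whitney U test at a loose
level (default alpha = 0.1, inclusive p <= alpha). On dense miRNA arrays
this removes the large mass of control probes that would otherwise dilute
the rank signatures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

#: default nonstringent significance level for the feature screen
DEFAULT_ALPHA = 0.1

#: largest group size for which the exact U distribution is used (untied data)
EXACT_MAX_N = 12


def drop_incomplete_probes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Restrict a matrix to probes with no missing (NaN) cells.

    Probe order and the sample set are preserved. Removing every probe is a
    hard error.
    """
    keep = matrix.notna().all(axis=1)
    if not keep.any():
        raise DataError("every probe has at least one missing value; nothing left to analyse")
    return matrix.loc[keep]


def virtual_control(matrix: pd.DataFrame) -> pd.Series:
    """Per-probe arithmetic mean across all samples.

    The matrix must be complete and strictly positive; otherwise the
    offending probe/sample is named in the error.
    """
    bad = ~(matrix > 0) | matrix.isna()
    if bad.to_numpy().any():
        i, j = next(zip(*bad.to_numpy().nonzero()))
        raise DataError(
            f"non-positive or missing intensity at probe {matrix.index[i]!r}, "
            f"sample {matrix.columns[j]!r}; run drop_incomplete_probes first "
            "and supply linear-scale positive intensities"
        )
    return matrix.mean(axis=1).rename("virtual_control")


def differential_transform(matrix: pd.DataFrame, control: pd.Series) -> pd.DataFrame:
    """Divide each profile probe-wise by the control profile."""
    if not matrix.index.equals(control.index):
        raise DataError("control profile probes do not match the matrix probes")
    if not (control > 0).all():
        raise DataError("control profile must be strictly positive")
    return matrix.div(control, axis=0)


def mann_whitney_p(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for group_a, p-value).

    The exact null distribution is used when both groups have at most 12
    observations and the pooled data is untied; otherwise the normal
    approximation with tie and continuity corrections. Deterministic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("Mann-Whitney test requires two non-empty groups")
    pooled = np.concatenate([a, b])
    untied = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and untied) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def select_features(matrix: pd.DataFrame, labels: pd.Series, alpha: float = DEFAULT_ALPHA,
                    *, inclusive: bool = True) -> pd.DataFrame:
    """Per-probe Mann-Whitney screen between control and affected samples.

    Samples labelled ``unknown`` (or absent from *labels*) are excluded from
    the test. Returns a DataFrame indexed by probe id with columns ``U``,
    ``p`` and boolean ``selected`` (p <= alpha by default; strict inequality
    with ``inclusive=False``).
    """
    if not 0 < alpha <= 1:
        raise ConfigError(f"alpha must be in (0, 1]; got {alpha}")
    labels = labels.reindex(matrix.columns).fillna("unknown")
    controls = matrix.columns[labels == "control"]
    affected = matrix.columns[labels == "affected"]
    if len(controls) == 0 or len(affected) == 0:
        raise DataError(
            "feature selection needs at least one control and one affected sample; "
            f"got {len(controls)} control, {len(affected)} affected"
        )
    a = matrix[controls].to_numpy()
    b = matrix[affected].to_numpy()
    U = np.empty(matrix.shape[0])
    p = np.empty(matrix.shape[0])
    for i in range(matrix.shape[0]):
        U[i], p[i] = mann_whitney_p(a[i], b[i])
    selected = p <= alpha if inclusive else p < alpha
    return pd.DataFrame({"U": U, "p": p, "selected": selected}, index=matrix.index)


def preprocess(matrix: pd.DataFrame, labels: pd.Series, alpha: float = DEFAULT_ALPHA,
               *, inclusive: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full preprocessing chain.

    Drops incomplete probes, computes the virtual control over *all* samples
    (known and unknown alike), applies the differential transform, and runs
    the feature screen on the known-labelled samples.

    Returns ``(differential matrix restricted to selected probes, report)``
    where *report* is the full per-probe selection table.
    """
    complete = drop_incomplete_probes(matrix)
    diff = differential_transform(complete, virtual_control(complete))
    report = select_features(diff, labels, alpha, inclusive=inclusive)
    chosen = report.index[report["selected"]]
    if len(chosen) == 0:
        raise DataError(f"no probe passed the feature screen at alpha={alpha}")
    return diff.loc[chosen], report
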