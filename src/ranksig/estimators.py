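"""Scikit-learn estimator layer.

These classes present the rank-signature method through the familiar
fit/transform/predict surface so it composes with sklearn pipelines and
model selection. They follow the sklearn input convention — ``X`` is
samples x features — and are thin orchestrators over the functional modules
(:mod:`~ranksig.preprocess`, :mod:`~ranksig.signature`,
:mod:`~ranksig.similarity`, :mod:`~ranksig.mapping`), which use the
microarray convention of probes x samples.

One departure from the usual inductive contract is intentional:
:class:`RankSignatureClassifier.predict` re-runs the virtual-control
transform and feature screen over the *combined* reference + query cohort
(the method diagnoses a new subject by adding their profile to the dataset
and reading off their position on the map), so predictions for a sample can
depend on which other samples are scored with it. Set
``recompute_control=False`` for a strictly inductive variant that freezes
the control profile and feature set at fit time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from . import mapping, preprocess, similarity
from .errors import DataError
from .mapping import ABSTAIN

__all__ = [
    "DifferentialTransformer",
    "MannWhitneyFeatureSelector",
    "SignatureDistance",
    "RankSignatureClassifier",
]


def _as_frame(X, *, prefix: str, feature_names=None) -> pd.DataFrame:
    """Coerce samples x features input to a DataFrame with string labels."""
    if isinstance(X, pd.DataFrame):
        frame = X.copy()
        frame.index = frame.index.map(str)
        frame.columns = frame.columns.map(str)
        return frame
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise DataError(f"expected a 2D samples x features array; got shape {arr.shape}")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(arr.shape[1])]
    index = [f"{prefix}{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=index, columns=list(feature_names))


def _validate_binary_y(y) -> tuple[pd.Series, np.ndarray]:
    y = pd.Series(np.asarray(y, dtype=object))
    classes = np.unique([v for v in y if v != "unknown"])
    if len(classes) != 2:
        raise DataError(f"need exactly two known classes in y; got {list(classes)}")
    return y, classes


class DifferentialTransformer(TransformerMixin, BaseEstimator):
    """Divide each profile by the fitted virtual control (per-probe mean).

    ``fit`` computes the control profile as the arithmetic mean of the
    training profiles; ``transform`` returns the probe-wise ratios. Input
    intensities must be linear-scale and strictly positive.
    """

    def fit(self, X, y=None):
        frame = _as_frame(X, prefix="s")
        self.control_ = preprocess.virtual_control(frame.T).to_numpy()
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns)
        return self

    def transform(self, X):
        check_is_fitted(self, "control_")
        frame = _as_frame(X, prefix="s", feature_names=self.feature_names_in_)
        if frame.shape[1] != self.n_features_in_:
            raise DataError(f"X has {frame.shape[1]} features; expected {self.n_features_in_}")
        out = frame.to_numpy(dtype=float) / self.control_[None, :]
        return pd.DataFrame(out, index=frame.index, columns=frame.columns) \
            if isinstance(X, pd.DataFrame) else out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "control_")
        return np.asarray(self.feature_names_in_, dtype=object)


class MannWhitneyFeatureSelector(SelectorMixin, BaseEstimator):
    """Keep features whose two-sided Mann-Whitney p between the two classes
    is at most ``alpha`` (strictly below with ``inclusive=False``).

    Samples labeled ``"unknown"`` are ignored by the test. The nonstringent
    default alpha of 0.1 deliberately applies no multiple-testing
    correction: the screen only removes uninformative probes before the
    rank-signature step, it does not claim per-probe significance.
    """

    def __init__(self, alpha: float = preprocess.DEFAULT_ALPHA, inclusive: bool = True):
        self.alpha = alpha
        self.inclusive = inclusive

    def fit(self, X, y):
        frame = _as_frame(X, prefix="s")
        y, classes = _validate_binary_y(y)
        labels = pd.Series(np.where(y.to_numpy() == classes[0], "control",
                                    np.where(y.to_numpy() == classes[1], "affected",
                                             "unknown")),
                           index=frame.index)
        report = preprocess.select_features(frame.T, labels, self.alpha,
                                            inclusive=self.inclusive)
        self.classes_ = classes
        self.pvalues_ = report["p"].to_numpy()
        self.statistics_ = report["U"].to_numpy()
        self.support_ = report["selected"].to_numpy()
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class SignatureDistance(TransformerMixin, BaseEstimator):
    """Pairwise signature distances, usable as a precomputed-metric step.

    ``fit`` stores the reference profiles (already feature-screened;
    differential or raw — the statistic only sees within-sample ranks);
    ``transform`` returns the query x reference distance matrix and
    ``fit_transform`` the square all-to-all matrix, e.g. for clustering with
    ``metric="precomputed"``.
    """

    def __init__(self, n_top: int = 25, n_bottom: int = 25):
        self.n_top = n_top
        self.n_bottom = n_bottom

    def fit(self, X, y=None):
        frame = _as_frame(X, prefix="ref")
        self.reference_ = frame
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        query = _as_frame(X, prefix="qry", feature_names=self.feature_names_in_)
        if list(query.columns) != list(self.reference_.columns):
            raise DataError("query features do not match the fitted reference features")
        ref = self.reference_
        overlap = query.index.intersection(ref.index)
        q = query
        if len(overlap) and query.index.equals(ref.index) and query.equals(ref):
            combined = ref
            q_ids, r_ids = list(ref.index), list(ref.index)
        else:
            q = query.rename(index=lambda s: f"query::{s}")
            combined = pd.concat([ref, q], axis=0)
            q_ids, r_ids = list(q.index), list(ref.index)
        dist, _ = similarity.distance_matrix(combined.T, self.n_top, self.n_bottom)
        return dist.loc[q_ids, r_ids].to_numpy()

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class RankSignatureClassifier(ClassifierMixin, BaseEstimator):
    """Phenotype diagnosis from the sample similarity map.

    The full procedure: virtual-control differential transform, Mann-Whitney
    feature screen at ``alpha``, top-``n_top``/bottom-``n_bottom`` rank
    signatures, bidirectional enrichment-score distances, a map keeping the
    smallest ``edge_percent`` % of distances, and a neighbor majority vote
    (inverse-distance-weighted when ``weighted=True``). A query sample whose
    vote ties, or that lands isolated on the map, receives the ``"abstain"``
    label; :meth:`score` counts abstentions as errors.

    Parameters
    ----------
    n_top, n_bottom : int
        Signature sizes n1 and n2 (most / least expressed probes).
    alpha : float
        Feature-screen significance level (p <= alpha, uncorrected).
    edge_percent : float
        Percentage N of smallest pairwise distances drawn as map edges.
    weighted : bool
        Weight neighbor votes by inverse distance.
    feature_selection : bool
        Disable to rank over all probes (the small-panel regime).
    inclusive_alpha : bool
        Use p <= alpha (True) or p < alpha (False).
    recompute_control : bool
        Recompute the virtual control and feature screen over the combined
        reference + query cohort at predict time (the transductive protocol).

    Attributes (after fit)
    ----------------------
    classes_, feature_names_in_, n_features_in_ : sklearn conventions.
    selection_report_ : per-probe U/p/selected table on the reference cohort.
    distances_ : square reference distance DataFrame.
    map_ : the reference similarity map (networkx Graph).
    communities_ : node -> community id over the reference map.
    community_labels_ : community id -> phenotype from the reference labels.
    """

    def __init__(self, n_top: int = 25, n_bottom: int = 25,
                 alpha: float = preprocess.DEFAULT_ALPHA, edge_percent: float = 10.0,
                 weighted: bool = False, feature_selection: bool = True,
                 inclusive_alpha: bool = True, recompute_control: bool = True):
        self.n_top = n_top
        self.n_bottom = n_bottom
        self.alpha = alpha
        self.edge_percent = edge_percent
        self.weighted = weighted
        self.feature_selection = feature_selection
        self.inclusive_alpha = inclusive_alpha
        self.recompute_control = recompute_control

    # -- internal helpers -------------------------------------------------

    def _prepare(self, matrix: pd.DataFrame, labels: pd.Series
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Preprocess a probes x samples matrix: complete probes, differential
        transform, optional feature screen using *labels*."""
        complete = preprocess.drop_incomplete_probes(matrix)
        diff = preprocess.differential_transform(
            complete, preprocess.virtual_control(complete))
        if self.feature_selection:
            report = preprocess.select_features(diff, labels, self.alpha,
                                                inclusive=self.inclusive_alpha)
            chosen = report.index[report["selected"]]
            if len(chosen) < self.n_top + self.n_bottom:
                raise DataError(
                    f"only {len(chosen)} probes passed the screen; the "
                    f"{self.n_top}+{self.n_bottom} signature does not fit"
                )
            return diff.loc[chosen], report
        report = pd.DataFrame({"U": np.nan, "p": np.nan, "selected": True},
                              index=diff.index)
        return diff, report

    def _roles(self) -> dict:
        """Map external class names to the internal control/affected roles.

        When y already uses the phenotype vocabulary the mapping is the
        identity (so sensitivity refers to the affected class); otherwise
        the lexicographically first class plays the control role.
        """
        if set(self.classes_) == {"control", "affected"}:
            return {"control": "control", "affected": "affected"}
        return {self.classes_[0]: "control", self.classes_[1]: "affected"}

    def _internal_labels(self, y: pd.Series) -> pd.Series:
        lut = self._roles()
        return y.map(lambda v: lut.get(v, "unknown"))

    def _external_labels(self, internal: pd.Series) -> np.ndarray:
        lut = {role: cls for cls, role in self._roles().items()}
        lut[ABSTAIN] = ABSTAIN
        return internal.map(lut).to_numpy()

    # -- sklearn surface --------------------------------------------------

    def fit(self, X, y):
        frame = _as_frame(X, prefix="ref")
        y, self.classes_ = _validate_binary_y(y)
        if len(y) != len(frame):
            raise DataError(f"X has {len(frame)} samples but y has {len(y)}")
        y.index = frame.index
        labels = self._internal_labels(y)

        self.X_ = frame
        self.y_ = y
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns)

        selected, self.selection_report_ = self._prepare(frame.T, labels)
        self.distances_, self.similarities_ = similarity.distance_matrix(
            selected, self.n_top, self.n_bottom)
        kept = mapping.threshold_edges(self.distances_, self.edge_percent)
        self.map_ = mapping.build_graph(self.distances_, kept)
        self.communities_ = mapping.detect_communities(self.map_)
        self.community_labels_ = mapping.label_clusters(self.communities_, labels)
        return self

    def predict(self, X):
        check_is_fitted(self, "X_")
        query = _as_frame(X, prefix="qry", feature_names=self.feature_names_in_)
        if list(query.columns) != list(self.X_.columns):
            raise DataError("query features do not match the fitted reference features")
        labels = self._internal_labels(self.y_)
        q = query.rename(index=lambda s: f"query::{s}")
        combined = pd.concat([self.X_, q], axis=0).T  # probes x samples
        all_labels = pd.concat([labels, pd.Series("unknown", index=q.index)])

        if self.recompute_control:
            selected, _ = self._prepare(combined, all_labels)
        else:
            complete = preprocess.drop_incomplete_probes(combined)
            control = preprocess.virtual_control(
                preprocess.drop_incomplete_probes(self.X_.T))
            common = complete.index.intersection(control.index)
            diff = preprocess.differential_transform(
                complete.loc[common], control.loc[common])
            chosen = self.selection_report_.index[self.selection_report_["selected"]]
            selected = diff.loc[diff.index.intersection(chosen)]

        dist, _ = similarity.distance_matrix(selected, self.n_top, self.n_bottom)
        kept = mapping.threshold_edges(dist, self.edge_percent)
        graph = mapping.build_graph(dist, kept)
        diagnosis = mapping.classify_majority(graph, labels, weighted=self.weighted,
                                              targets=list(q.index))
        return self._external_labels(diagnosis["predicted"])

    def score(self, X, y):
        """Accuracy with abstentions (ties, isolated nodes) counted wrong."""
        pred = self.predict(X)
        return float(np.mean(pred == np.asarray(y, dtype=object)))

    def evaluate_loo(self, *, weighted: bool | None = None) -> dict[str, float]:
        """Leave-one-out metrics on the fitted reference map: each node is
        diagnosed from its neighbors' true labels with its own hidden."""
        check_is_fitted(self, "map_")
        w = self.weighted if weighted is None else weighted
        _, metrics = mapping.evaluate_loo(self.map_, self._internal_labels(self.y_),
                                          weighted=w)
        return metrics
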