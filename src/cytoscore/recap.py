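"""Cross-panel cluster recapitulation and label transfer.

Clusters discovered on a full antibody panel are reconstructed from the
markers shared with an external cohort: a random forest (500 trees) is
trained to predict the full-panel cluster label from the shared markers
only, its fidelity is quantified with the adjusted Rand index on a
stratified holdout, and the trained forest then assigns labels (with
class probabilities) to the external cohort's cells. Cells whose top
class probability does not exceed a confidence threshold (default 0.8,
strict) are flagged as unretained. A one-vs-rest forest per cluster
with permutation importance identifies which shared markers carry each
cluster's identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .events import EventMatrix

__all__ = [
    "adjusted_rand_index",
    "ClusterRecapitulator",
    "train_recap_forest",
    "evaluate_recapitulation",
    "transfer_labels",
    "TransferResult",
    "per_cluster_importance",
]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions.

    Computed from the label contingency table N = (n_ij):

        ARI = (sum_ij C(n_ij,2) - E) / (0.5*(sum_i C(a_i,2) + sum_j C(b_j,2)) - E)

    with E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2). Equals 1 for
    identical partitions (up to relabeling), ~0 for independent ones,
    and can be negative for anti-correlated partitions. When the
    denominator vanishes (both partitions trivial) 1.0 is returned.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("ARI requires at least 2 elements")

    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        x = np.asarray(x, dtype=np.float64)
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0:
        return 1.0
    return float((sum_ij - expected) / denom)


@dataclass
class TransferResult:
    """Per-event label transfer outcome for an external cohort."""

    labels: np.ndarray        # predicted cluster per event
    max_probability: np.ndarray
    retained: np.ndarray      # bool, max_probability > threshold (strict)
    threshold: float

    @property
    def retention_rate(self) -> float:
        return float(self.retained.mean()) if self.retained.size else 0.0


class ClusterRecapitulator(ClassifierMixin, BaseEstimator):
    """Random-forest reconstruction of a clustering from shared markers.

    Parameters
    ----------
    shared_markers : list of str, optional
        Columns to train on when X is passed as a DataFrame or
        EventMatrix; with a plain array, all columns are used.
    n_trees : int, default 500
        Forest size.
    threshold : float, default 0.8
        Confidence cut for :meth:`transfer` (strict >).
    test_size : float, default 0.2
        Stratified holdout fraction used to estimate the reconstruction
        adjusted Rand index; the final forest is refit on all events.

    Attributes
    ----------
    classes_ : cluster labels retained for training.
    holdout_ari_ : reconstruction ARI on the stratified holdout.
    dropped_classes_ : singleton clusters excluded from training.
    """

    def __init__(
        self,
        shared_markers: list[str] | None = None,
        n_trees: int = 500,
        threshold: float = 0.8,
        test_size: float = 0.2,
        random_state: int = 0,
    ):
        self.shared_markers = shared_markers
        self.n_trees = n_trees
        self.threshold = threshold
        self.test_size = test_size
        self.random_state = random_state

    def _extract(self, X) -> np.ndarray:
        if isinstance(X, EventMatrix):
            X = X.to_frame()
        if isinstance(X, pd.DataFrame):
            if self.shared_markers is not None:
                missing = [m for m in self.shared_markers if m not in X.columns]
                if missing:
                    raise KeyError(f"missing shared markers: {missing}")
                X = X[self.shared_markers]
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if self.shared_markers is not None and X.shape[1] != len(self.shared_markers):
            raise ValueError(
                "array width does not match shared_markers; pass a DataFrame "
                "or EventMatrix for name-based selection"
            )
        return X

    def fit(self, X, y):
        Xs = self._extract(X)
        y = np.asarray(y)
        if Xs.shape[0] != y.shape[0]:
            raise ValueError("labels must align with events")

        classes, counts = np.unique(y, return_counts=True)
        singletons = classes[counts < 2]
        if singletons.size:
            warnings.warn(
                f"clusters with a single event dropped: {singletons.tolist()}",
                UserWarning,
            )
            keep = ~np.isin(y, singletons)
            Xs, y = Xs[keep], y[keep]

        X_tr, X_te, y_tr, y_te = train_test_split(
            Xs, y, test_size=self.test_size, stratify=y,
            random_state=self.random_state,
        )
        probe = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state, n_jobs=1
        ).fit(X_tr, y_tr)
        self.holdout_ari_ = adjusted_rand_index(y_te, probe.predict(X_te))

        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state, n_jobs=1
        ).fit(Xs, y)
        self.classes_ = self.forest_.classes_
        self.dropped_classes_ = singletons.tolist()
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(self._extract(X))

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(self._extract(X))

    def transfer(self, X, threshold: float | None = None) -> TransferResult:
        """Assign labels to external events with a confidence cut."""
        thr = self.threshold if threshold is None else threshold
        proba = self.predict_proba(X)
        idx = np.argmax(proba, axis=1)
        max_p = proba[np.arange(proba.shape[0]), idx]
        return TransferResult(
            labels=self.classes_[idx],
            max_probability=max_p,
            retained=max_p > thr,
            threshold=thr,
        )


def train_recap_forest(
    events, labels, shared_markers=None, n_trees: int = 500, seed: int = 0
) -> ClusterRecapitulator:
    """Functional wrapper over :class:`ClusterRecapitulator`."""
    return ClusterRecapitulator(
        shared_markers=shared_markers, n_trees=n_trees, random_state=seed
    ).fit(events, labels)


def evaluate_recapitulation(model: ClusterRecapitulator, events, labels) -> float:
    """ARI between the model's predictions and a reference labeling."""
    return adjusted_rand_index(np.asarray(labels), model.predict(events))


def transfer_labels(
    model: ClusterRecapitulator, external_events, threshold: float = 0.8
) -> TransferResult:
    """Apply a trained recapitulation forest to an external cohort."""
    return model.transfer(external_events, threshold=threshold)


def per_cluster_importance(
    events,
    labels,
    shared_markers: list[str] | None = None,
    n_permutations: int = 10,
    n_trees: int = 100,
    test_size: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Shared-marker permutation importance per cluster (one vs rest).

    For each cluster a binary forest separates it from all other events;
    marker importance is the mean holdout-accuracy drop over
    ``n_permutations`` shuffles of that marker. Holdout accuracy and
    sensitivity (recall on the cluster) are reported alongside.

    Returns a tidy DataFrame with columns cluster, marker, importance,
    accuracy, sensitivity.
    """
    if isinstance(events, EventMatrix):
        events = events.to_frame()
    if isinstance(events, pd.DataFrame):
        markers = shared_markers or list(events.columns)
        X = events[markers].to_numpy(dtype=float)
    else:
        X = np.asarray(events, dtype=float)
        markers = shared_markers or [f"M{j}" for j in range(X.shape[1])]
    y = np.asarray(labels)

    rows = []
    for cluster in np.unique(y):
        target = (y == cluster).astype(int)
        if target.sum() < 2 or (target.size - target.sum()) < 2:
            warnings.warn(f"cluster {cluster} too small; skipped", UserWarning)
            continue
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, target, test_size=test_size, stratify=target, random_state=seed
        )
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        ).fit(X_tr, y_tr)
        pred = forest.predict(X_te)
        accuracy = float((pred == y_te).mean())
        pos = y_te == 1
        sensitivity = float((pred[pos] == 1).mean()) if pos.any() else np.nan
        imp = permutation_importance(
            forest, X_te, y_te, n_repeats=n_permutations, random_state=seed,
            scoring="accuracy",
        )
        for j, marker in enumerate(markers):
            rows.append(
                {
                    "cluster": cluster,
                    "marker": marker,
                    "importance": float(imp.importances_mean[j]),
                    "accuracy": accuracy,
                    "sensitivity": sensitivity,
                }
            )
    return pd.DataFrame(rows)
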