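"""Arcsinh transformation and empirical-Bayes batch correction.

Raw CyTOF ion counts are variance-stabilised with the inverse hyperbolic
sine, x -> asinh(x / cofactor) (cofactor 5, the community convention for
mass cytometry). Batch / cohort effects are then removed on the arcsinh
scale with a parametric empirical-Bayes location/scale model: per marker
the data are standardised by the grand model, per-batch location and
scale estimates are shrunk toward their across-marker priors, divided
out, and the grand location/scale restored.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .events import ARCSINH, RAW, EventMatrix

__all__ = [
    "arcsinh_transform",
    "ComBat",
    "combat_correct",
    "pca_batch_check",
]


def arcsinh_transform(events: EventMatrix, cofactor: float = 5.0) -> EventMatrix:
    """Apply x -> asinh(x / cofactor) to a raw event matrix.

    The transform is strictly monotone, behaves linearly near zero and
    logarithmically for large counts, and approximately normalises
    per-cluster marker distributions.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if events.transform_state == ARCSINH:
        raise ValueError(
            f"sample {events.sample_id}: already arcsinh-transformed"
        )
    return replace(
        events,
        values=np.arcsinh(events.values / cofactor),
        transform_state=ARCSINH,
        cofactor=cofactor,
    )


class ComBat(TransformerMixin, BaseEstimator):
    """Parametric empirical-Bayes location/scale batch correction.

    Model per marker g, batch i, event j:

        x_ijg = alpha_g + gamma_ig + delta_ig * eps_ijg

    Batch location gamma_ig gets a Gaussian prior across markers, batch
    scale delta_ig^2 an inverse-gamma prior; posterior estimates are
    found by the standard fixed-point iteration and used to adjust each
    batch to the grand location/scale.

    Parameters
    ----------
    recenter : bool, default True
        After adjustment, restore each marker's pooled mean exactly
        (residual shrinkage otherwise leaves an O(1/n) offset).
    max_iter, tol : fixed-point iteration controls.

    Attributes
    ----------
    batches_ : list of batch labels seen in fit.
    grand_mean_ : (n_markers,) grand location per marker.
    pooled_var_ : (n_markers,) pooled residual variance per marker.
    gamma_star_, delta_sq_star_ : dict batch -> (n_markers,) posterior
        location / squared-scale adjustments.
    skipped_ : indices of markers left unadjusted (zero pooled variance).
    """

    def __init__(self, recenter: bool = True, max_iter: int = 100, tol: float = 1e-8):
        self.recenter = recenter
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None, *, batch):
        X = check_array(X, dtype=float)
        batch = np.asarray(batch)
        if batch.shape[0] != X.shape[0]:
            raise ValueError("batch labels must align with rows of X")
        self.batches_ = [b for b in dict.fromkeys(batch.tolist())]
        counts = {b: int(np.sum(batch == b)) for b in self.batches_}
        if any(n < 2 for n in counts.values()):
            small = [b for b, n in counts.items() if n < 2]
            raise ValueError(f"batches with fewer than 2 events: {small}")
        n_total = X.shape[0]
        n_markers = X.shape[1]

        if len(self.batches_) < 2:
            warnings.warn("single batch: ComBat is the identity", UserWarning)
            self.grand_mean_ = X.mean(axis=0)
            self.pooled_var_ = X.var(axis=0)
            self.gamma_star_ = {self.batches_[0]: np.zeros(n_markers)}
            self.delta_sq_star_ = {self.batches_[0]: np.ones(n_markers)}
            self.skipped_ = np.arange(n_markers)
            self._identity = True
            return self

        self._identity = False
        batch_means = np.vstack([X[batch == b].mean(axis=0) for b in self.batches_])
        n_i = np.array([counts[b] for b in self.batches_], dtype=float)
        grand = (n_i[:, None] * batch_means).sum(axis=0) / n_total
        resid = X - np.vstack([batch_means[self.batches_.index(b)] for b in batch])
        pooled = (resid**2).sum(axis=0) / n_total

        skipped = np.where(pooled <= 0)[0]
        if skipped.size:
            warnings.warn(
                f"markers with zero pooled variance skipped: {skipped.tolist()}",
                UserWarning,
            )
        ok = pooled > 0
        denom = np.sqrt(np.where(ok, pooled, 1.0))

        Z = (X - grand) / denom
        gamma_hat = np.vstack([Z[batch == b].mean(axis=0) for b in self.batches_])
        delta_hat = np.vstack([Z[batch == b].var(axis=0, ddof=1) for b in self.batches_])

        self.gamma_star_ = {}
        self.delta_sq_star_ = {}
        for i, b in enumerate(self.batches_):
            g_bar = gamma_hat[i, ok].mean()
            t2 = gamma_hat[i, ok].var(ddof=1)
            d = delta_hat[i, ok]
            v_bar, s2 = d.mean(), d.var(ddof=1)
            # inverse-gamma hyperparameters by method of moments
            lam = (v_bar**2 + 2 * s2) / s2 if s2 > 0 else np.inf
            theta = (v_bar**3 + v_bar * s2) / s2 if s2 > 0 else 0.0

            g_star = gamma_hat[i].copy()
            d_star = delta_hat[i].copy()
            if np.isfinite(lam) and t2 > 0:
                n_b = n_i[i]
                Zb = Z[batch == b]
                g_new = gamma_hat[i].copy()
                d_new = delta_hat[i].copy()
                for _ in range(self.max_iter):
                    g_old, d_old = g_new.copy(), d_new.copy()
                    g_new = (n_b * t2 * gamma_hat[i] + d_new * g_bar) / (
                        n_b * t2 + d_new
                    )
                    sse = ((Zb - g_new) ** 2).sum(axis=0)
                    d_new = (theta + 0.5 * sse) / (n_b / 2 + lam - 1)
                    if (
                        np.max(np.abs(g_new - g_old)) < self.tol
                        and np.max(np.abs(d_new - d_old)) < self.tol
                    ):
                        break
                g_star, d_star = g_new, d_new
            g_star = np.where(ok, g_star, 0.0)
            d_star = np.where(ok & (d_star > 0), d_star, 1.0)
            self.gamma_star_[b] = g_star
            self.delta_sq_star_[b] = d_star

        self.grand_mean_ = grand
        self.pooled_var_ = pooled
        self.skipped_ = skipped
        self._scale_ = denom
        self._ok_ = ok
        return self

    def transform(self, X, batch):
        check_is_fitted(self, "grand_mean_")
        X = check_array(X, dtype=float)
        batch = np.asarray(batch)
        if self._identity:
            return X.copy()
        out = X.copy()
        for b in np.unique(batch):
            if b not in self.gamma_star_:
                raise KeyError(f"batch {b!r} not seen during fit")
            rows = batch == b
            Z = (X[rows] - self.grand_mean_) / self._scale_
            Zadj = (Z - self.gamma_star_[b]) / np.sqrt(self.delta_sq_star_[b])
            adj = Zadj * self._scale_ + self.grand_mean_
            out[rows] = np.where(self._ok_, adj, X[rows])
        if self.recenter:
            out[:, self._ok_] += (
                self.grand_mean_[self._ok_] - out[:, self._ok_].mean(axis=0)
            )
        return out

    def fit_transform(self, X, y=None, *, batch):
        return self.fit(X, batch=batch).transform(X, batch=batch)


def combat_correct(
    matrices: list[EventMatrix], batch_labels: list[str] | None = None
) -> tuple[list[EventMatrix], ComBat]:
    """Batch-correct a set of arcsinh-transformed event matrices.

    Events are pooled across samples within batch (the sample is not a
    model term); corrected matrices preserve per-sample shapes and event
    order. ``batch_labels`` defaults to each matrix's recorded batch.
    """
    if batch_labels is None:
        batch_labels = [m.batch for m in matrices]
        if any(b is None for b in batch_labels):
            raise ValueError("matrices without batch metadata; pass batch_labels")
    if len(batch_labels) != len(matrices):
        raise ValueError("one batch label per matrix required")
    markers = matrices[0].markers
    for m in matrices:
        if m.transform_state != ARCSINH:
            raise ValueError(f"sample {m.sample_id}: arcsinh-transform first")
        if m.markers != markers:
            raise ValueError("all matrices must share one marker panel")

    X = np.vstack([m.values for m in matrices])
    per_event_batch = np.concatenate(
        [np.repeat(b, m.n_events) for m, b in zip(matrices, batch_labels)]
    )
    model = ComBat().fit(X, batch=per_event_batch)
    Xc = model.transform(X, batch=per_event_batch)

    corrected = []
    start = 0
    for m, b in zip(matrices, batch_labels):
        stop = start + m.n_events
        corrected.append(replace(m, values=Xc[start:stop], batch=b))
        start = stop
    return corrected, model


def pca_batch_check(
    matrices: list[EventMatrix],
    batch_labels: list[str] | None = None,
    n_components: int = 5,
    random_state: int = 0,
) -> tuple[np.ndarray, float]:
    """Quantify residual batch structure in principal-component space.

    Pools all events, computes a PCA, and for each component reports the
    fraction of score variance explained by batch membership (the R^2 of
    a batch-indicator fit, i.e. between-batch sum of squares over total).
    Returns the per-component array and its maximum; values near 0 mean
    the batches are comparable along that axis.
    """
    if batch_labels is None:
        batch_labels = [m.batch for m in matrices]
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X = np.vstack([m.values for m in matrices])
    batch = np.concatenate(
        [np.repeat(b, m.n_events) for m, b in zip(matrices, batch_labels)]
    )
    if len(np.unique(batch)) < 2:
        raise ValueError("need at least two batches")
    if X.shape[0] < n_components:
        raise ValueError("fewer events than requested components")
    scores = PCA(n_components=n_components, random_state=random_state).fit_transform(X)
    r2 = np.empty(n_components)
    for k in range(n_components):
        s = scores[:, k]
        ss_tot = np.sum((s - s.mean()) ** 2)
        ss_between = sum(
            np.sum(s[batch == b].shape[0] * (s[batch == b].mean() - s.mean()) ** 2)
            for b in np.unique(batch)
        )
        r2[k] = ss_between / ss_tot if ss_tot > 0 else 0.0
    return r2, float(r2.max())
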