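"""Graph clustering with a resolution search targeting a cluster count.

Events (arcsinh scale) are embedded in a k-nearest-neighbour graph
(Euclidean metric, k = 30 by default) and partitioned by Leiden
community detection. Because the resolution parameter, not the cluster
count, is the algorithm's native dial, a grid search over resolutions
(default 0.5..3.0, step 0.02) picks the resolution whose achieved number
of communities is closest to the requested target; ties go to the
smallest resolution (coarser, more stable partitions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.neighbors import kneighbors_graph
from sklearn.utils.validation import check_array, check_is_fitted

from .events import EventMatrix

__all__ = [
    "LeidenResolutionSearch",
    "cluster_with_resolution_search",
    "downsample_events",
    "compute_centroids",
    "zscore_profiles",
    "ClusterCentroids",
]


@dataclass
class ClusterCentroids:
    """Per-cluster mean marker profiles.

    ``profiles`` is a clusters x markers DataFrame (index = cluster id);
    ``counts`` the event count per cluster. ``zscored`` records whether
    columns have been standardised across clusters (sample sd, n-1).
    """

    profiles: pd.DataFrame
    counts: pd.Series
    zscored: bool = False
    dropped_markers: list[str] = field(default_factory=list)

    @property
    def markers(self) -> list[str]:
        return list(self.profiles.columns)


class LeidenResolutionSearch(ClusterMixin, BaseEstimator):
    """kNN-graph Leiden clustering tuned to a target cluster count.

    Parameters
    ----------
    target_k : int
        Requested number of clusters.
    r_min, r_max, r_step : float
        Resolution grid (inclusive of ``r_min``; extends to the last
        grid point <= ``r_max`` + half a step).
    n_neighbors : int
        Neighbours in the kNN graph.
    random_state : int
        Seed passed to the Leiden optimiser; fixes the partition.

    Attributes
    ----------
    labels_ : (n_events,) integer labels, contiguous 0..K-1, clusters
        numbered by descending size.
    resolution_ : chosen resolution.
    n_clusters_ : achieved number of clusters.
    grid_record_ : list of (resolution, achieved_k) over the whole grid.
    """

    def __init__(
        self,
        target_k: int = 26,
        r_min: float = 0.5,
        r_max: float = 3.0,
        r_step: float = 0.02,
        n_neighbors: int = 30,
        n_iterations: int = 2,
        random_state: int = 0,
    ):
        self.target_k = target_k
        self.r_min = r_min
        self.r_max = r_max
        self.r_step = r_step
        self.n_neighbors = n_neighbors
        self.n_iterations = n_iterations
        self.random_state = random_state

    def _grid(self) -> np.ndarray:
        if not (self.r_min < self.r_max) or self.r_step <= 0:
            raise ValueError("require r_min < r_max and r_step > 0")
        n = int(round((self.r_max - self.r_min) / self.r_step))
        grid = self.r_min + self.r_step * np.arange(n + 1)
        return grid[grid <= self.r_max + self.r_step / 2]

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n = X.shape[0]
        if self.target_k < 1 or n < self.target_k:
            raise ValueError("need at least target_k events")
        grid = self._grid()

        if np.allclose(X, X[0]):
            warnings.warn("all events identical: single cluster", UserWarning)
            self.labels_ = np.zeros(n, dtype=int)
            self.resolution_ = float(grid[0])
            self.n_clusters_ = 1
            self.grid_record_ = [(float(r), 1) for r in grid]
            return self

        k = min(self.n_neighbors, n - 1)
        adj = kneighbors_graph(X, n_neighbors=k, mode="connectivity")
        sources, targets = adj.nonzero()
        g = ig.Graph(n=n, edges=list(zip(sources.tolist(), targets.tolist())),
                     directed=False)
        g.simplify()

        record: list[tuple[float, int]] = []
        partitions: dict[float, np.ndarray] = {}
        for r in grid:
            part = leidenalg.find_partition(
                g,
                leidenalg.RBConfigurationVertexPartition,
                resolution_parameter=float(r),
                seed=self.random_state,
                n_iterations=self.n_iterations,
            )
            labels = np.asarray(part.membership)
            record.append((float(r), int(labels.max()) + 1))
            partitions[float(r)] = labels

        ks = np.array([k_ for _, k_ in record])
        rs = np.array([r_ for r_, _ in record])
        best = int(np.argmin(np.abs(ks - self.target_k)))  # ties -> smallest r
        labels = partitions[float(rs[best])]

        # relabel by descending cluster size for stable naming
        sizes = np.bincount(labels)
        order = np.argsort(-sizes, kind="stable")
        remap = np.empty_like(order)
        remap[order] = np.arange(order.size)
        self.labels_ = remap[labels]
        self.resolution_ = float(rs[best])
        self.n_clusters_ = int(ks[best])
        self.grid_record_ = record
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_with_resolution_search(
    events: EventMatrix | np.ndarray,
    target_k: int = 26,
    r_min: float = 0.5,
    r_max: float = 3.0,
    r_step: float = 0.02,
    k_neighbors: int = 30,
    seed: int = 0,
) -> LeidenResolutionSearch:
    """Functional wrapper over :class:`LeidenResolutionSearch`."""
    X = events.values if isinstance(events, EventMatrix) else events
    return LeidenResolutionSearch(
        target_k=target_k, r_min=r_min, r_max=r_max, r_step=r_step,
        n_neighbors=k_neighbors, random_state=seed,
    ).fit(X)


def downsample_events(
    matrices: list[EventMatrix],
    group_labels: list[str],
    cap: int = 100_000,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Pool events with a per-group uniform random cap.

    At most ``cap`` events are kept per group (all of them when fewer
    are available), sampled without replacement. Returns the pooled
    matrix and a provenance table mapping each kept row to its sample,
    source row and group.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if len(group_labels) != len(matrices):
        raise ValueError("one group label per matrix required")
    rng = np.random.default_rng(seed)
    markers = matrices[0].markers

    blocks: list[np.ndarray] = []
    prov_rows: list[pd.DataFrame] = []
    for group in dict.fromkeys(group_labels):
        members = [m for m, g in zip(matrices, group_labels) if g == group]
        total = sum(m.n_events for m in members)
        if total == 0:
            warnings.warn(f"group {group!r} has no events; skipped", UserWarning)
            continue
        keep = min(cap, total)
        chosen = np.sort(rng.choice(total, size=keep, replace=False))
        offsets = np.cumsum([0] + [m.n_events for m in members])
        for i, m in enumerate(members):
            local = chosen[(chosen >= offsets[i]) & (chosen < offsets[i + 1])] - offsets[i]
            if local.size == 0:
                continue
            blocks.append(m.values[local])
            prov_rows.append(
                pd.DataFrame(
                    {"sample_id": m.sample_id, "row": local, "group": group}
                )
            )
    pooled = np.vstack(blocks) if blocks else np.empty((0, len(markers)))
    provenance = (
        pd.concat(prov_rows, ignore_index=True)
        if prov_rows
        else pd.DataFrame(columns=["sample_id", "row", "group"])
    )
    return pooled, provenance


def compute_centroids(
    X: np.ndarray | EventMatrix,
    labels: np.ndarray,
    markers: list[str] | None = None,
) -> ClusterCentroids:
    """Mean marker profile and event count per cluster."""
    if isinstance(X, EventMatrix):
        markers = X.markers
        X = X.values
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("labels must align with event rows")
    if markers is None:
        markers = [f"M{j}" for j in range(X.shape[1])]
    present = np.unique(labels)
    if labels.size and present.max() >= 0:
        expected = np.arange(int(present.max()) + 1)
        empty = np.setdiff1d(expected, present)
        if empty.size:
            warnings.warn(f"empty clusters excluded: {empty.tolist()}", UserWarning)
    rows = {int(c): X[labels == c].mean(axis=0) for c in present}
    profiles = pd.DataFrame.from_dict(rows, orient="index", columns=markers).sort_index()
    counts = pd.Series(
        {int(c): int(np.sum(labels == c)) for c in present}, name="count"
    ).sort_index()
    return ClusterCentroids(profiles=profiles, counts=counts)


def zscore_profiles(centroids: ClusterCentroids) -> ClusterCentroids:
    """Standardise each marker across clusters (sample sd, n-1).

    Cosine matching compares profile *directions*; z-scoring removes
    per-marker location/scale so that direction reflects which clusters
    are high or low for each marker. Markers constant across clusters
    carry no direction and are dropped with a warning.
    """
    if centroids.zscored:
        raise ValueError("profiles are already z-scored")
    K = centroids.profiles.shape[0]
    if K < 2:
        raise ValueError("z-scoring undefined for fewer than 2 clusters")
    mu = centroids.profiles.mean(axis=0)
    sd = centroids.profiles.std(axis=0, ddof=1)
    constant = sd.index[sd <= 0].tolist()
    if constant:
        warnings.warn(f"constant markers dropped: {constant}", UserWarning)
    keep = sd.index[sd > 0]
    z = (centroids.profiles[keep] - mu[keep]) / sd[keep]
    return ClusterCentroids(
        profiles=z, counts=centroids.counts.copy(), zscored=True,
        dropped_markers=constant,
    )
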