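"""Cross-dataset cluster correspondence by cosine similarity.

Clusters found independently in two cohorts are matched by comparing
the directions of their z-scored centroid profiles: for every source
cluster the target cluster with the highest cosine similarity is
reported. Matching is greedy per source cluster — two source clusters
may claim the same target; such collisions are surfaced in the result
rather than silently resolved. An optimal one-to-one assignment
(Hungarian) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .clustering import ClusterCentroids

__all__ = ["cosine_similarity", "match_clusters", "ClusterMatch"]


def cosine_similarity(u, v) -> float:
    """dot(u, v) / (||u|| ||v||); errors on zero vectors."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape or u.size == 0:
        raise ValueError("vectors must be non-empty and of equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class ClusterMatch:
    """Source -> target cluster correspondence."""

    mapping: dict[int, tuple[int, float]]   # source -> (target, similarity)
    similarity: pd.DataFrame                # source x target cosine matrix
    collisions: dict[int, list[int]] = field(default_factory=dict)
    low_quality: list[int] = field(default_factory=list)
    floor: float = 0.5
    one_to_one: bool = False

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": s,
                "target": t,
                "similarity": sim,
                "low_quality": s in self.low_quality,
            }
            for s, (t, sim) in self.mapping.items()
        ]
        return pd.DataFrame(rows)


def match_clusters(
    source: ClusterCentroids,
    target: ClusterCentroids,
    floor: float = 0.5,
    one_to_one: bool = False,
) -> ClusterMatch:
    """Match source clusters to target clusters by profile direction.

    Both inputs must be z-scored centroid sets over the same markers in
    the same order (resolve aliases upstream). Matches with similarity
    below ``floor`` are flagged low-quality but still reported.
    """
    sm, tm = list(source.profiles.columns), list(target.profiles.columns)
    if sm != tm:
        diff = sorted(set(sm).symmetric_difference(tm))
        if diff:
            raise ValueError(f"marker sets differ between centroid sets: {diff}")
        raise ValueError(f"marker order differs between centroid sets: {sm} vs {tm}")
    if not (source.zscored and target.zscored):
        raise ValueError("match_clusters expects z-scored centroid profiles")

    S = source.profiles.to_numpy()
    T = target.profiles.to_numpy()
    sn = S / np.linalg.norm(S, axis=1, keepdims=True)
    tn = T / np.linalg.norm(T, axis=1, keepdims=True)
    sim = pd.DataFrame(
        sn @ tn.T, index=source.profiles.index, columns=target.profiles.index
    )

    if one_to_one:
        ri, ci = linear_sum_assignment(-sim.to_numpy())
        pairs = {
            int(sim.index[i]): int(sim.columns[j]) for i, j in zip(ri, ci)
        }
        mapping = {
            s: (t, float(sim.loc[s, t])) for s, t in pairs.items()
        }
    else:
        mapping = {}
        for s in sim.index:
            t = sim.loc[s].idxmax()
            mapping[int(s)] = (int(t), float(sim.loc[s, t]))

    claimed: dict[int, list[int]] = {}
    for s, (t, _) in mapping.items():
        claimed.setdefault(t, []).append(s)
    collisions = {t: ss for t, ss in claimed.items() if len(ss) > 1}
    low_quality = [s for s, (_, v) in mapping.items() if v < floor]

    return ClusterMatch(
        mapping=mapping,
        similarity=sim,
        collisions=collisions,
        low_quality=low_quality,
        floor=floor,
        one_to_one=one_to_one,
    )
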