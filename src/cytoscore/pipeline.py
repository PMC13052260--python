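"""End-to-end orchestration of the two-cohort analysis.

Chains the stages in their canonical order — arcsinh transform, ComBat
across cohorts on the shared panel, resolution-search clustering of the
discovery cohort on its full panel, random-forest recapitulation from
shared markers, confidence-thresholded label transfer to the external
cohort, cosine centroid matching, per-sample feature tables, two-group
differential testing, ROC evaluation, and benefit scoring — and records
a manifest with per-stage seeds, content hashes and warnings.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarker import ScoreThresholds, benefit_score, roc_auc
from .clustering import (
    LeidenResolutionSearch,
    compute_centroids,
    downsample_events,
    zscore_profiles,
)
from .events import EventMatrix
from .features import group_compare, sample_features
from .matching import match_clusters
from .preprocessing import arcsinh_transform, combat_correct
from .recap import ClusterRecapitulator

__all__ = ["PipelineParams", "RunManifest", "run_pipeline"]

STAGES = [
    "transform", "combat", "cluster", "recapitulate", "transfer",
    "match", "features", "diff", "roc", "score",
]


@dataclass
class PipelineParams:
    """Tunable knobs of the standard analysis."""

    cofactor: float = 5.0
    target_k: int = 26
    r_min: float = 0.5
    r_max: float = 3.0
    r_step: float = 0.02
    k_neighbors: int = 30
    downsample_cap: int = 100_000
    n_trees: int = 500
    transfer_threshold: float = 0.8
    group_col: str = "group"
    groups: tuple[str, str] = ("non_irAE", "irAE")
    roc_features: tuple[str, ...] = (
        "holistic.CXCR3", "holistic.CCR6", "holistic.PD-1", "holistic.TIGIT",
    )
    roc_orientation: str = "lower"
    score_columns: tuple[str, str, str] = ("freq.C19", "freq.C22", "expr.C07.CCR6")
    score_thresholds: ScoreThresholds = field(default_factory=ScoreThresholds)
    seed: int = 0


@dataclass
class RunManifest:
    """Record of one pipeline run: config, per-stage seeds and hashes."""

    stages: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    version: str = __version__

    def add(self, name: str, payload, seed: int | None = None,
            warnings_: list[str] | None = None) -> None:
        self.stages.append(
            {
                "stage": name,
                "hash": _digest(payload),
                "seed": seed,
                "warnings": warnings_ or [],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "config": self.config, "stages": self.stages},
            indent=2, default=str,
        )


def _digest(payload) -> str:
    h = hashlib.sha256()
    for part in payload if isinstance(payload, (list, tuple)) else [payload]:
        if isinstance(part, np.ndarray):
            h.update(np.ascontiguousarray(part).tobytes())
        elif isinstance(part, pd.DataFrame):
            h.update(part.to_csv(index=True).encode())
        elif isinstance(part, pd.Series):
            h.update(part.to_csv().encode())
        else:
            h.update(json.dumps(part, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


def run_pipeline(
    cohort1: list[EventMatrix],
    meta1: pd.DataFrame,
    cohort4: list[EventMatrix],
    meta4: pd.DataFrame,
    shared_markers: list[str],
    params: PipelineParams | None = None,
    plasma: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> RunManifest:
    """Run the full two-cohort analysis and return its manifest.

    ``cohort1`` is the discovery cohort (full panel) whose clustering is
    recapitulated; ``cohort4`` the external validation cohort carrying
    at least the shared markers. Raises at the failing stage with its
    name; artifacts of completed stages are preserved when ``out_dir``
    is given.
    """
    params = params or PipelineParams()
    seeds = _stage_seeds(params.seed)
    manifest = RunManifest(config={**asdict(params)})
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _write(name: str, obj) -> None:
        if out is None:
            return
        path = out / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path)
        else:
            path.write_text(obj)

    def _run(stage, fn):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                payload = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest.add(stage, payload, seed=seeds[stage],
                     warnings_=[str(w.message) for w in caught])
        if out is not None:
            (out / "manifest.json").write_text(manifest.to_json())
        return payload

    state: dict = {}

    def stage_transform():
        state["c1"] = [arcsinh_transform(m, params.cofactor) for m in cohort1]
        state["c4"] = [arcsinh_transform(m, params.cofactor) for m in cohort4]
        return [m.values for m in state["c1"]] + [m.values for m in state["c4"]]

    def stage_combat():
        shared1 = [m.select_markers(shared_markers) for m in state["c1"]]
        shared4 = [m.select_markers(shared_markers) for m in state["c4"]]
        batches = ["cohort1"] * len(shared1) + ["cohort4"] * len(shared4)
        corrected, model = combat_correct(shared1 + shared4, batches)
        state["c1_shared"] = corrected[: len(shared1)]
        state["c4_shared"] = corrected[len(shared1):]
        return [m.values for m in corrected]

    def stage_cluster():
        groups = meta1.set_index("sample_id")[params.group_col]
        glabels = [groups[m.sample_id] for m in state["c1"]]
        pooled, prov = downsample_events(
            state["c1"], glabels, cap=params.downsample_cap, seed=seeds["cluster"]
        )
        search = LeidenResolutionSearch(
            target_k=params.target_k, r_min=params.r_min, r_max=params.r_max,
            r_step=params.r_step, n_neighbors=params.k_neighbors,
            random_state=seeds["cluster"],
        ).fit(pooled)
        state["pooled"], state["prov"], state["search"] = pooled, prov, search
        _write("cluster_labels.csv",
               prov.assign(cluster=search.labels_))
        _write("grid_record.json",
               json.dumps({"resolution": search.resolution_,
                           "achieved_k": search.n_clusters_,
                           "grid": search.grid_record_}, indent=2))
        return [search.labels_, np.array(search.grid_record_)]

    def stage_recapitulate():
        by_sample = {m.sample_id: m for m in state["c1_shared"]}
        rows = np.vstack(
            [
                by_sample[sid].values[r]
                for sid, r in zip(state["prov"]["sample_id"], state["prov"]["row"])
            ]
        )
        model = ClusterRecapitulator(
            n_trees=params.n_trees, threshold=params.transfer_threshold,
            random_state=seeds["recapitulate"],
        ).fit(rows, state["search"].labels_)
        state["recap"] = model
        # propagate labels to every discovery-cohort event
        state["c1_labels"] = {
            m.sample_id: model.predict(m.values) for m in state["c1_shared"]
        }
        return [model.holdout_ari_]

    def stage_transfer():
        res = {
            m.sample_id: state["recap"].transfer(m.values)
            for m in state["c4_shared"]
        }
        state["transfer"] = res
        rates = {sid: r.retention_rate for sid, r in res.items()}
        _write("transfer_summary.csv",
               pd.DataFrame({"retention_rate": rates}))
        return [np.concatenate([r.labels for r in res.values()]),
                np.concatenate([r.max_probability for r in res.values()])]

    def stage_match():
        X1 = np.vstack([m.values for m in state["c1_shared"]])
        l1 = np.concatenate(
            [state["c1_labels"][m.sample_id] for m in state["c1_shared"]]
        )
        c1_cent = zscore_profiles(
            compute_centroids(X1, l1, markers=shared_markers)
        )
        keep = [
            (m.values[state["transfer"][m.sample_id].retained],
             state["transfer"][m.sample_id].labels[state["transfer"][m.sample_id].retained])
            for m in state["c4_shared"]
        ]
        X4 = np.vstack([v for v, _ in keep])
        l4 = np.concatenate([l for _, l in keep])
        c4_cent = zscore_profiles(compute_centroids(X4, l4, markers=shared_markers))
        common = [m for m in c1_cent.markers if m in c4_cent.markers]
        c1_cent.profiles = c1_cent.profiles[common]
        c4_cent.profiles = c4_cent.profiles[common]
        match = match_clusters(c4_cent, c1_cent)
        state["match"] = match
        _write("cluster_match.csv", match.as_frame())
        _write("similarity_matrix.csv", match.similarity)
        return [match.similarity]

    def stage_features():
        table = sample_features(
            state["c1"], state["c1_labels"], meta1, plasma=plasma
        )
        state["features"] = table
        _write("features.csv", table)
        return [table]

    def stage_diff():
        comparison = group_compare(
            state["features"], params.group_col, params.groups
        )
        state["diff"] = comparison
        _write("group_comparison.csv", comparison)
        return [comparison]

    def stage_roc():
        y = (state["features"][params.group_col] == params.groups[1]).astype(int)
        results = {}
        for feat in params.roc_features:
            if feat not in state["features"].columns:
                warnings.warn(f"ROC feature {feat!r} not in table; skipped",
                              UserWarning)
                continue
            vals = pd.to_numeric(state["features"][feat], errors="coerce")
            ok = vals.notna()
            res = roc_auc(vals[ok].to_numpy(), y[ok].to_numpy(),
                          orientation=params.roc_orientation)
            results[feat] = {
                "auc": res.auc, "ci": [res.ci_low, res.ci_high],
                "p": res.p_value, "orientation": res.orientation,
            }
        state["roc"] = results
        _write("roc_report.json", json.dumps(results, indent=2))
        return [results]

    def stage_score():
        cols = params.score_columns
        missing = [c for c in cols if c not in state["features"].columns]
        cards = []
        if missing:
            warnings.warn(f"scoring columns missing, stage skipped: {missing}",
                          UserWarning)
        else:
            for _, row in state["features"].iterrows():
                card = benefit_score(
                    float(row[cols[0]]), float(row[cols[1]]),
                    float(row[cols[2]]) if pd.notna(row[cols[2]]) else -np.inf,
                    thresholds=params.score_thresholds,
                )
                cards.append(
                    {"sample_id": row["sample_id"], **card.points,
                     "total": card.total, "decision": card.decision}
                )
        scores = pd.DataFrame(cards)
        state["scores"] = scores
        _write("scorecards.csv", scores)
        return [scores]

    stage_fns = {
        "transform": stage_transform, "combat": stage_combat,
        "cluster": stage_cluster, "recapitulate": stage_recapitulate,
        "transfer": stage_transfer, "match": stage_match,
        "features": stage_features, "diff": stage_diff,
        "roc": stage_roc, "score": stage_score,
    }
    for stage in STAGES:
        _run(stage, stage_fns[stage])
    state["manifest"] = manifest
    manifest.state = state  # expose stage outputs for programmatic use
    return manifest
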