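"""Per-sample feature tables and two-group comparisons.

Each sample is summarised by its cluster frequencies (percent of the
sample's events), per-cluster per-marker mean arcsinh expression,
holistic (all-events) marker means, and optional plasma analyte
concentrations. Group contrasts (irAE vs non_irAE, PR vs SD/PD, or any
custom labelling) use the equal-variance two-tailed Student's t-test
per feature, with Benjamini-Hochberg q-values reported alongside the
raw p-values for transparency (the primary readout is the raw p, as is
conventional for exploratory CyTOF screens).

Feature columns are namespaced: ``freq.C07`` (cluster frequency, %),
``expr.C07.CCR6`` (cluster marker mean), ``holistic.CXCR3`` (all-event
marker mean), ``plasma.CXCL9`` (pg/mL).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .events import EventMatrix

__all__ = [
    "cluster_name",
    "sample_features",
    "group_compare",
    "classify_onset",
    "cohort_summary",
]

EARLY, LATE, NOT_APPLICABLE = "early", "late", "not_applicable"


def cluster_name(cluster: int, prefix: str = "C") -> str:
    """Stable display name for a cluster id (0-based id -> C01, C02, ...)."""
    return f"{prefix}{cluster + 1:02d}"


def sample_features(
    matrices: list[EventMatrix],
    labels: dict[str, np.ndarray],
    meta: pd.DataFrame,
    plasma: pd.DataFrame | None = None,
    cluster_prefix: str = "C",
) -> pd.DataFrame:
    """Build the per-sample feature table.

    Parameters
    ----------
    matrices : event matrices (arcsinh scale recommended).
    labels : sample_id -> per-event cluster labels covering every event.
    meta : sample metadata (must contain ``sample_id``); joined onto the
        output.
    plasma : optional sample x analyte table (index = sample_id).

    Frequencies are percentages of each sample's own events and sum to
    100 per sample; a cluster missing from a sample has frequency 0 and
    missing (NaN) expression values.
    """
    all_clusters = sorted(
        {int(c) for lab in labels.values() for c in np.unique(lab)}
    )
    rows = []
    for m in matrices:
        if m.sample_id not in labels:
            raise KeyError(f"no labels for sample {m.sample_id}")
        lab = np.asarray(labels[m.sample_id])
        if lab.shape[0] != m.n_events:
            raise ValueError(f"labels do not cover all events of {m.sample_id}")
        if m.n_events == 0:
            warnings.warn(f"sample {m.sample_id} has zero events; excluded",
                          UserWarning)
            continue
        row: dict[str, float | str] = {"sample_id": m.sample_id}
        for c in all_clusters:
            name = cluster_name(c, cluster_prefix)
            in_c = lab == c
            row[f"freq.{name}"] = 100.0 * in_c.sum() / m.n_events
            if in_c.any():
                means = m.values[in_c].mean(axis=0)
                for j, marker in enumerate(m.markers):
                    row[f"expr.{name}.{marker}"] = means[j]
            else:
                for marker in m.markers:
                    row[f"expr.{name}.{marker}"] = np.nan
        holistic = m.values.mean(axis=0)
        for j, marker in enumerate(m.markers):
            row[f"holistic.{marker}"] = holistic[j]
        rows.append(row)

    table = pd.DataFrame(rows)
    if plasma is not None:
        p = plasma.add_prefix("plasma.").reset_index()
        table = table.merge(p, on="sample_id", how="left")
    return table.merge(meta, on="sample_id", how="left")


def group_compare(
    table: pd.DataFrame,
    group_col: str,
    groups: tuple[str, str],
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Two-tailed equal-variance Student's t-test per feature.

    ``groups = (reference, case)``; the reported direction is the sign
    of mean(case) - mean(reference) ("decreased" when the case group is
    lower). Missing values (e.g. expression of a cluster absent from a
    sample) are excluded pairwise. Features with fewer than two values
    in either group, or zero variance in both, are skipped with a
    warning.

    Returns a DataFrame indexed by feature with group means/sds, t, df,
    p, BH q and direction.
    """
    ref, case = groups
    if features is None:
        features = [
            c
            for c in table.columns
            if c.split(".")[0] in {"freq", "expr", "holistic", "plasma"}
        ]
    ref_rows = table[table[group_col] == ref]
    case_rows = table[table[group_col] == case]
    if len(ref_rows) == 0 or len(case_rows) == 0:
        raise ValueError(f"empty group among {groups}")

    out = []
    skipped = []
    for feat in features:
        x = pd.to_numeric(ref_rows[feat], errors="coerce").dropna().to_numpy()
        y = pd.to_numeric(case_rows[feat], errors="coerce").dropna().to_numpy()
        if x.size < 2 or y.size < 2:
            skipped.append(feat)
            continue
        pooled_var = np.concatenate([x - x.mean(), y - y.mean()]).var()
        if pooled_var == 0:
            if x.mean() == y.mean():
                t_stat, p = 0.0, 1.0
            else:
                skipped.append(feat)
                continue
        else:
            t_stat, p = stats.ttest_ind(y, x, equal_var=True)
        diff = y.mean() - x.mean()
        out.append(
            {
                "feature": feat,
                f"mean_{ref}": x.mean(),
                f"sd_{ref}": x.std(ddof=1),
                f"mean_{case}": y.mean(),
                f"sd_{case}": y.std(ddof=1),
                "t": float(t_stat),
                "df": x.size + y.size - 2,
                "p": float(p),
                "direction": "increased" if diff > 0 else ("decreased" if diff < 0 else "unchanged"),
            }
        )
    if skipped:
        warnings.warn(f"features skipped (too few values or constant): "
                      f"{len(skipped)}", UserWarning)
    result = pd.DataFrame(out).set_index("feature") if out else pd.DataFrame()
    if len(result):
        result["q"] = multipletests(result["p"], method="fdr_bh")[1]
    return result


def classify_onset(onset_day: float | None) -> str:
    """Classify irAE onset relative to the first checkpoint-inhibitor dose.

    0-90 days inclusive is early-onset; strictly more than 90 days is
    late-onset. ``None``/NaN (no irAE) maps to ``"not_applicable"``.
    """
    if onset_day is None or (isinstance(onset_day, float) and np.isnan(onset_day)):
        return NOT_APPLICABLE
    if onset_day < 0:
        raise ValueError("onset day must be non-negative")
    return EARLY if onset_day <= 90 else LATE


def cohort_summary(meta: pd.DataFrame) -> dict:
    """Onset / grade / type breakdown of the irAE patients in a cohort.

    Expects columns ``grade`` (0 = no irAE), ``onset_day`` (NaN when no
    irAE) and optionally ``irae_type``. Percentages are 100 * count /
    denominator rounded to one decimal; empty denominators yield None.

    Returns a dict with overall early/late onset percentages, the
    Grade >= 3 share within each onset stratum, and the early-onset
    share within each irAE type.
    """
    def pct(k: int, n: int) -> float | None:
        return round(100.0 * k / n, 1) if n else None

    irae = meta[meta["grade"].fillna(0) >= 1].copy()
    irae["onset_class"] = [classify_onset(d) for d in irae["onset_day"]]
    n = len(irae)
    early = irae[irae["onset_class"] == EARLY]
    late = irae[irae["onset_class"] == LATE]

    summary = {
        "n_irae": n,
        "n_early": len(early),
        "n_late": len(late),
        "early_onset_pct": pct(len(early), n),
        "late_onset_pct": pct(len(late), n),
        "grade3plus_in_early_pct": pct(int((early["grade"] >= 3).sum()), len(early)),
        "grade3plus_in_late_pct": pct(int((late["grade"] >= 3).sum()), len(late)),
        "by_type": {},
    }
    if "irae_type" in irae.columns:
        for t, sub in irae.groupby("irae_type"):
            sub_early = (sub["onset_class"] == EARLY).sum()
            summary["by_type"][t] = {
                "n": len(sub),
                "n_early": int(sub_early),
                "early_pct": pct(int(sub_early), len(sub)),
            }
    return summary
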