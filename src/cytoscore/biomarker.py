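"""ROC biomarker evaluation and the 4-point benefit score.

AUC is the tie-corrected pairwise concordance probability (ties credit
1/2), computed from midranks — mathematically identical to the
trapezoidal area under the empirical ROC curve. Confidence intervals
use the DeLong structural-components variance by default (Hanley-McNeil
available as an option), and the p-value tests AUC = 0.5 against the
DeLong normal approximation.

The benefit score combines three baseline features into 0-4 points:
Response Cluster 19 frequency > 1.219 % scores 2 points, Cluster 22
frequency > 0.025 % scores 1 point, and mean CCR6 expression in C07
> 1.238 (arcsinh units) scores 1 point; 2 or more points mark the
regimen as beneficial, otherwise discouraging. All thresholds are
strict and configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RocResult",
    "roc_auc",
    "BivariateModel",
    "fit_bivariate_logistic",
    "ScoreThresholds",
    "ScoreCard",
    "benefit_score",
    "youden_threshold",
]


@dataclass
class RocResult:
    """Empirical ROC curve with AUC, CI and a test against AUC = 0.5."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    orientation: str
    n_pos: int
    n_neg: int
    ci_method: str = "delong"


def _curve(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-scores, kind="mergesort")
    s, yy = scores[order], y[order]
    # step only at distinct thresholds
    distinct = np.r_[np.where(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(yy)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / yy.sum()]
    fpr = np.r_[0.0, fps / (yy.size - yy.sum())]
    return fpr, tpr


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from midrank structural components."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.r_[pos, neg])
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (all_ranks[:m] - pos_ranks) / n          # components for positives
    v10 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # components for negatives
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def roc_auc(
    scores,
    labels,
    orientation: str = "higher",
    ci_method: str = "delong",
    alpha: float = 0.05,
) -> RocResult:
    """Evaluate a continuous score as a binary classifier.

    Parameters
    ----------
    scores, labels : array-likes; labels are binary (1 = positive class).
    orientation : {"higher", "lower", "auto"}
        "higher": larger score predicts the positive class; "lower"
        negates the scores first (the convention for markers *decreased*
        in the at-risk group, e.g. CXCR3/CCR6/PD-1/TIGIT); "auto" picks
        whichever direction gives AUC >= 0.5 and records it.
    ci_method : {"delong", "hanley-mcneil"}.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if not set(np.unique(y)) <= {0, 1} or len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes (0 and 1)")
    if orientation not in {"higher", "lower", "auto"}:
        raise ValueError(f"unknown orientation {orientation!r}")

    if orientation == "auto":
        auc_h, _ = _delong_variance(scores, y)
        orientation = "higher" if auc_h >= 0.5 else "lower"
    s = scores if orientation == "higher" else -scores

    auc, var = _delong_variance(s, y)
    m, n = int(y.sum()), int((1 - y).sum())
    if ci_method == "delong":
        se = np.sqrt(var)
    elif ci_method == "hanley-mcneil":
        q1 = auc / (2 - auc)
        q2 = 2 * auc * auc / (1 + auc)
        se = np.sqrt(
            (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2))
            / (m * n)
        )
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    z = stats.norm.ppf(1 - alpha / 2)
    ci_low = float(np.clip(auc - z * se, 0.0, 1.0))
    ci_high = float(np.clip(auc + z * se, 0.0, 1.0))
    se_null = np.sqrt(var)
    if se_null > 0:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se_null))
    else:  # degenerate variance (e.g. perfect separation)
        p = float(np.nan) if auc == 0.5 else 0.0
    fpr, tpr = _curve(s, y)
    return RocResult(
        fpr=fpr, tpr=tpr, auc=float(auc), ci_low=ci_low, ci_high=ci_high,
        p_value=p, orientation=orientation, n_pos=m, n_neg=n,
        ci_method=ci_method,
    )


@dataclass
class BivariateModel:
    """Two-predictor logistic model with the ROC of its fitted risk."""

    intercept: float
    coef: tuple[float, float]
    fitted_probabilities: np.ndarray
    roc: RocResult
    z_values: tuple[float, float]
    separation: bool = False
    converged: bool = True
    predictors: tuple[str, str] = ("x1", "x2")


def fit_bivariate_logistic(
    x1, x2, labels, names: tuple[str, str] = ("x1", "x2")
) -> BivariateModel:
    """Maximum-likelihood logistic regression on two predictors.

    Fit by iteratively reweighted least squares (Newton). Complete
    separation (diverging coefficients / non-convergence) is detected;
    the model is then refit with a small L2 ridge penalty and flagged.
    The ROC of the fitted probabilities is attached — this is the
    "bivariant model" AUC of combined-marker prediction.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(labels).astype(int)
    if not (x1.shape == x2.shape == y.shape):
        raise ValueError("x1, x2 and labels must be aligned 1-D arrays")
    if y.size < 4:
        raise ValueError("need at least 4 observations")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    for name, x in zip(names, (x1, x2)):
        if np.ptp(x) == 0:
            raise ValueError(f"constant predictor: {name}")

    X = sm.add_constant(np.column_stack([x1, x2]))
    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = np.asarray(fit.params)
            bse = np.asarray(fit.bse)
            converged = bool(fit.mle_retvals.get("converged", True))
            if not converged or not np.all(np.isfinite(bse)) or np.any(
                np.abs(params[1:]) > 1e3
            ):
                separation = True
        except Exception:
            separation = True
    if separation:
        warnings.warn(
            "complete or quasi-complete separation detected; refitting with "
            "a small ridge penalty",
            UserWarning,
        )
        fit = sm.Logit(y, X).fit_regularized(
            method="l1", alpha=np.array([0.0, 1e-4, 1e-4]), disp=0, maxiter=500
        )
        # fall back to a plain L2-regularised Newton step if needed
        params = np.asarray(fit.params)
        bse = np.full(3, np.nan)

    prob = 1.0 / (1.0 + np.exp(-(X @ params)))
    roc = roc_auc(prob, y, orientation="higher")
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = params / bse
    return BivariateModel(
        intercept=float(params[0]),
        coef=(float(params[1]), float(params[2])),
        fitted_probabilities=prob,
        roc=roc,
        z_values=(float(zvals[1]), float(zvals[2])),
        separation=separation,
        converged=converged and not separation,
        predictors=names,
    )


@dataclass
class ScoreThresholds:
    """Strict cut-offs for the 4-point benefit score (shipped defaults)."""

    rc19_freq: float = 1.219       # % of events; > scores 2 points
    c22_freq: float = 0.025        # % of events; > scores 1 point
    ccr6_c07: float = 1.238        # arcsinh mean;  > scores 1 point
    rc19_points: int = 2
    c22_points: int = 1
    ccr6_points: int = 1
    beneficial_min: int = 2


@dataclass
class ScoreCard:
    """Outcome of the benefit score for one patient."""

    inputs: dict = field(default_factory=dict)
    points: dict = field(default_factory=dict)
    total: int = 0
    decision: str = "discouraging"


def benefit_score(
    freq_rc19: float,
    freq_c22: float,
    ccr6_c07: float,
    thresholds: ScoreThresholds | None = None,
) -> ScoreCard:
    """Score a baseline sample on the 4-point benefit scale.

    All comparisons are strictly greater-than; a value exactly at a
    cut-off scores no points. Two or more total points mark the regimen
    beneficial.
    """
    t = thresholds or ScoreThresholds()
    if freq_rc19 < 0 or freq_c22 < 0:
        raise ValueError("frequencies must be non-negative")
    points = {
        "rc19": t.rc19_points if freq_rc19 > t.rc19_freq else 0,
        "c22": t.c22_points if freq_c22 > t.c22_freq else 0,
        "ccr6_c07": t.ccr6_points if ccr6_c07 > t.ccr6_c07 else 0,
    }
    total = sum(points.values())
    return ScoreCard(
        inputs={
            "freq_rc19": freq_rc19,
            "freq_c22": freq_c22,
            "ccr6_c07": ccr6_c07,
        },
        points=points,
        total=total,
        decision="beneficial" if total >= t.beneficial_min else "discouraging",
    )


def youden_threshold(scores, labels, orientation: str = "higher") -> float:
    """Threshold maximising TPR - FPR (offered as a utility only; the
    shipped score cut-offs are fixed defaults, not re-derived)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    s = scores if orientation == "higher" else -scores
    order = np.argsort(-s, kind="mergesort")
    ss, yy = s[order], y[order]
    tps = np.cumsum(yy)
    fps = np.cumsum(1 - yy)
    j = tps / yy.sum() - fps / (yy.size - yy.sum())
    best = int(np.argmax(j))
    thr = ss[best]
    return float(thr if orientation == "higher" else -thr)
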