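"""Diagnostic-marker meta-analysis.

Pools per-study diagnostic effects (odds ratios for dichotomous extractions,
mean differences for continuous IHC scores) across the studies reporting a
marker, quantifies between-study heterogeneity (Cochran's Q, I², τ² by the
DerSimonian–Laird moment estimator) and summarises discrimination with a
Moses–Littenberg summary ROC curve.  A selection filter then keeps markers
that pool convincingly: enough studies, homogeneous, significant, large
effect and high summary AUC.

Study-level inputs come either from :class:`Study2x2` (marker-positive /
marker-negative counts in dysplastic and non-dysplastic groups) or from
:class:`StudyMeans` (group means / SDs of a continuous score).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

Z_95 = 1.959964  # two-sided 95% normal quantile

__all__ = [
    "Study2x2",
    "StudyMeans",
    "EffectEstimate",
    "PooledEffect",
    "SrocResult",
    "MarkerResult",
    "SelectionCriteria",
    "study_log_or",
    "study_mean_diff",
    "pool",
    "sroc",
    "select_markers",
    "read_study_table",
    "forest_table",
]


class UndefinedEffectError(ValueError):
    """Raised when a study's effect cannot be estimated (empty margin)."""


class SrocUndefinedError(ValueError):
    """Raised when the fitted sROC slope makes the summary curve undefined."""

    def __init__(self, intercept: float, slope: float):
        self.intercept = intercept
        self.slope = slope
        super().__init__(
            f"sROC curve undefined for |slope| >= 1 (a={intercept:.4g}, b={slope:.4g})"
        )


@dataclass(frozen=True)
class Study2x2:
    """One study's 2x2 extraction.

    a: marker-positive, dysplastic; b: marker-negative, dysplastic;
    c: marker-positive, non-dysplastic; d: marker-negative, non-dysplastic.
    """

    study_id: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError(f"negative count in study {self.study_id!r}")
        if sum(counts) == 0:
            raise ValueError(f"all counts zero in study {self.study_id!r}")


@dataclass(frozen=True)
class StudyMeans:
    """One study's continuous-score extraction (group 1 dysplastic)."""

    study_id: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self) -> None:
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError(f"negative SD in study {self.study_id!r}")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError(f"group size < 2 in study {self.study_id!r}")


@dataclass(frozen=True)
class EffectEstimate:
    y: float
    v: float
    scale: str  # "log_or" | "mean_diff"
    study_id: str = ""

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError("effect variance must be positive")


@dataclass(frozen=True)
class PooledEffect:
    estimate: float  # back-transformed (OR) for log_or scale
    ci_low: float
    ci_high: float
    theta: float  # working-scale pooled effect
    se: float
    p_value: float  # pooled-effect z test
    Q: float
    df: int
    p_het: float
    I2: float  # percent, clamped to [0, 100]
    tau2: float
    k: int
    model: str
    scale: str


@dataclass(frozen=True)
class SrocResult:
    intercept_a: float
    slope_b: float
    auc: float


@dataclass
class MarkerResult:
    """Everything the selection filter needs for one marker."""

    marker: str
    pooled: PooledEffect
    sroc: SrocResult | None = None


@dataclass(frozen=True)
class SelectionCriteria:
    """Marker-panel filter: all enabled criteria must hold."""

    min_studies: int = 3
    min_p_het: float = 0.05
    max_p_pooled: float = 0.05
    min_sauc: float = 0.75
    min_or: float = 5.0


def study_log_or(study: Study2x2) -> EffectEstimate:
    """Log odds ratio with Haldane–Anscombe 0.5 correction on zero cells.

    Raises :class:`UndefinedEffectError` when a margin is empty (no
    dysplastic or no marker-positive subjects at all), where even the
    corrected OR has no interpretation.
    """
    a, b, c, d = study.a, study.b, study.c, study.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise UndefinedEffectError(
            f"study {study.study_id!r} has an empty margin; odds ratio undefined"
        )
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    y = math.log((a * d) / (b * c))
    v = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return EffectEstimate(y=y, v=v, scale="log_or", study_id=study.study_id)


def study_mean_diff(study: StudyMeans) -> EffectEstimate:
    """Unstandardised mean difference with its sampling variance."""
    if study.sd1 == 0 and study.sd2 == 0:
        raise ValueError(
            f"study {study.study_id!r} has zero variance in both groups"
        )
    y = study.mean1 - study.mean2
    v = study.sd1**2 / study.n1 + study.sd2**2 / study.n2
    return EffectEstimate(y=y, v=v, scale="mean_diff", study_id=study.study_id)


def pool(effects: Sequence[EffectEstimate], model: str = "dl_random") -> PooledEffect:
    """Inverse-variance pooling, fixed-effect or DerSimonian–Laird random.

    The DL between-study variance is the moment estimator
    τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) with fixed-effect weights w=1/v;
    random-effects weights are then 1/(v+τ²).  Heterogeneity is summarised by
    I² = max(0, 100·(Q − df)/Q) and a χ²(df) test of Q.  When τ̂² = 0 the
    random-effects result coincides exactly with the fixed-effect one.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("cannot pool an empty list of effects")
    scales = {e.scale for e in effects}
    if len(scales) > 1:
        raise ValueError(f"cannot pool mixed scales {sorted(scales)}")
    scale = effects[0].scale
    if model not in ("fixed", "dl_random"):
        raise ValueError(f"unknown pooling model {model!r}")

    y = np.array([e.y for e in effects])
    v = np.array([e.v for e in effects])
    k = len(effects)
    w = 1.0 / v
    theta_fe = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - theta_fe) ** 2))
    df = k - 1
    if df > 0:
        p_het = float(stats.chi2.sf(Q, df))
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
        I2 = max(0.0, 100.0 * (Q - df) / Q) if Q > 0 else 0.0
    else:
        p_het, tau2, I2 = 1.0, 0.0, 0.0

    if model == "fixed" or tau2 == 0.0:
        w_star = w
    else:
        w_star = 1.0 / (v + tau2)
    theta = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(math.sqrt(1.0 / np.sum(w_star)))
    lo, hi = theta - Z_95 * se, theta + Z_95 * se
    p_value = float(2.0 * stats.norm.sf(abs(theta) / se))

    if scale == "log_or":
        est, ci_low, ci_high = math.exp(theta), math.exp(lo), math.exp(hi)
    else:
        est, ci_low, ci_high = theta, lo, hi
    return PooledEffect(
        estimate=est, ci_low=ci_low, ci_high=ci_high,
        theta=theta, se=se, p_value=p_value,
        Q=Q, df=df, p_het=p_het, I2=min(I2, 100.0),
        tau2=0.0 if model == "fixed" else tau2,
        k=k, model=model, scale=scale,
    )


def _rates(study: Study2x2) -> tuple[float, float]:
    """(TPR, FPR) with a 0.5 continuity correction when any cell is zero."""
    a, b, c, d = study.a, study.b, study.c, study.d
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if a + b == 0 or c + d == 0:
        raise UndefinedEffectError(
            f"study {study.study_id!r}: TPR/FPR undefined (empty group)"
        )
    return a / (a + b), c / (c + d)


def sroc(studies: Sequence[Study2x2], fpr_step: float = 0.001) -> SrocResult:
    """Moses–Littenberg summary ROC.

    Regresses D = logit(TPR) − logit(FPR) on S = logit(TPR) + logit(FPR) by
    unweighted least squares, then integrates the implied TPR(FPR) curve,
    logit(TPR) = (a + (1+b)·logit(FPR)) / (1−b), over an FPR grid by the
    trapezoid rule.  Study order does not matter.
    """
    if len(studies) < 2:
        raise ValueError("sROC needs at least 2 studies")
    tpr_fpr = [_rates(s) for s in studies]
    D = np.array([logit(t) - logit(f) for t, f in tpr_fpr])
    S = np.array([logit(t) + logit(f) for t, f in tpr_fpr])
    s_var = float(np.var(S))
    if s_var < 1e-12:
        b = 0.0
        a = float(np.mean(D))
    else:
        b = float(np.cov(S, D, bias=True)[0, 1] / s_var)
        a = float(np.mean(D) - b * np.mean(S))
    if abs(b) >= 1.0:
        raise SrocUndefinedError(a, b)
    fpr = np.arange(fpr_step, 1.0, fpr_step)
    tpr = expit((a + (1.0 + b) * logit(fpr)) / (1.0 - b))
    auc = float(np.trapezoid(tpr, fpr))
    return SrocResult(intercept_a=a, slope_b=b, auc=min(max(auc, 0.0), 1.0))


def select_markers(
    results: Iterable[MarkerResult],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> list[str]:
    """Apply the marker-panel filter.

    A marker passes when it has enough studies, non-significant
    heterogeneity, a significant pooled effect and — for dichotomous
    extractions, where they are defined — pooled OR above the OR floor and
    summary AUC above the AUC floor.  Continuous (mean-difference) markers
    are judged on study count, homogeneity and significance only.
    """
    selected = []
    for r in results:
        p = r.pooled
        if p.k < criteria.min_studies:
            continue
        if p.p_het < criteria.min_p_het:
            continue
        if p.p_value >= criteria.max_p_pooled:
            continue
        if p.scale == "log_or":
            if p.estimate <= criteria.min_or:
                continue
            if r.sroc is None or r.sroc.auc <= criteria.min_sauc:
                continue
        selected.append(r.marker)
    return selected


def read_study_table(path) -> dict[str, list[Study2x2] | list[StudyMeans]]:
    """Read a per-marker study table from CSV.

    Dichotomous rows carry columns ``study_id, marker, a, b, c, d``;
    continuous rows carry ``study_id, marker, mean1, sd1, n1, mean2, sd2, n2``.
    Returns marker -> list of studies (one kind per marker).
    """
    df = pd.read_csv(path, comment="#")
    out: dict[str, list] = {}
    dichotomous = {"a", "b", "c", "d"}.issubset(df.columns)
    continuous = {"mean1", "sd1", "n1"}.issubset(df.columns)
    if not (dichotomous or continuous):
        raise ValueError(
            "study table needs columns a,b,c,d or mean1,sd1,n1,mean2,sd2,n2"
        )
    for _, row in df.iterrows():
        if dichotomous and not (continuous and pd.isna(row.get("a"))):
            study = Study2x2(str(row["study_id"]), int(row["a"]), int(row["b"]),
                             int(row["c"]), int(row["d"]))
        else:
            study = StudyMeans(str(row["study_id"]),
                               float(row["mean1"]), float(row["sd1"]), int(row["n1"]),
                               float(row["mean2"]), float(row["sd2"]), int(row["n2"]))
        out.setdefault(str(row["marker"]), []).append(study)
    return out


def forest_table(effects: Sequence[EffectEstimate], pooled: PooledEffect) -> pd.DataFrame:
    """Forest-plot-ready table: per-study effect, 95% CI and pooling weight."""
    rows = []
    wsum = sum(1.0 / (e.v + pooled.tau2) for e in effects)
    for e in effects:
        se = math.sqrt(e.v)
        lo, hi = e.y - Z_95 * se, e.y + Z_95 * se
        if e.scale == "log_or":
            est, lo, hi = math.exp(e.y), math.exp(lo), math.exp(hi)
        else:
            est = e.y
        rows.append({
            "study_id": e.study_id, "estimate": est,
            "ci_low": lo, "ci_high": hi,
            "weight_pct": 100.0 * (1.0 / (e.v + pooled.tau2)) / wsum,
        })
    rows.append({
        "study_id": "POOLED", "estimate": pooled.estimate,
        "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
        "weight_pct": 100.0,
    })
    return pd.DataFrame(rows)
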