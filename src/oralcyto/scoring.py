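"""Immunostain quantification: cell grading, composite scores, marker
features, the healthy-baseline nomogram and ROC utilities.

Mirrors the manual scoring model used in marker-based cytopathology:
each cell receives an intensity grade on the even scale {0, 2, 4, 6}
after background correction, a slide/patient receives a composite score
(percentage positivity × modal intensity, range 0–600), and per-marker
feature sets (average/maximum grade, nuclear positivity percentages,
percentage of strongly stained cells) summarise a patient.  The nomogram
tabulates healthy-baseline means per anatomical site × age group so that
lesion values can be read against a mean + 2·SD reference bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

SITES = ("buccal", "tongue", "gingiva")
AGE_GROUPS = ("<=40", ">40")
GRADES = (0, 2, 4, 6)
DEFAULT_THRESHOLDS = (0.25, 0.5, 0.75)

__all__ = [
    "CellGrade",
    "IhcScore",
    "MarkerFeatureSet",
    "NomogramTable",
    "correct_intensity",
    "grade_intensity",
    "ihc_score",
    "marker_features",
    "build_nomogram",
    "roc_auc",
    "age_group",
]


@dataclass(frozen=True)
class CellGrade:
    intensity_grade: int
    nuclear_positive: bool = False

    def __post_init__(self) -> None:
        if self.intensity_grade not in GRADES:
            raise ValueError(f"grade must be one of {GRADES}")


@dataclass(frozen=True)
class IhcScore:
    percent_positive: float
    modal_intensity: int
    final_score: float  # percent_positive * modal_intensity, in [0, 600]


@dataclass
class MarkerFeatureSet:
    """Per-patient marker features; ``None`` marks a missing channel."""

    SNA1avg: float | None = None
    SNA1max: float | None = None
    CD44max: float | None = None
    CD44Npos: float | None = None  # percent of cells nuclear-positive
    CD44pct: float | None = None   # percent with grade > 4 (i.e. grade 6)
    CYCD1Npos: float | None = None
    MAAavg: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return dict(vars(self))


def correct_intensity(cell_mean: float, background_mean: float) -> float:
    """Background-corrected mean intensity, clamped at zero."""
    if not (0.0 <= cell_mean <= 1.0 and 0.0 <= background_mean <= 1.0):
        raise ValueError("intensities must lie in [0, 1]")
    return max(0.0, cell_mean - background_mean)


def background_mean(channel: np.ndarray, cell_labels: np.ndarray) -> float:
    """Mean intensity of pixels outside every cell label."""
    outside = cell_labels == 0
    if not outside.any():
        return 0.0
    return float(channel[outside].mean())


def grade_intensity(
    corrected: float, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> int:
    """Map a corrected intensity onto the even grade scale {0, 2, 4, 6}.

    Grade 0 below t1, 2 in [t1, t2), 4 in [t2, t3), 6 at >= t3.  The three
    cut points must be strictly ascending.
    """
    t1, t2, t3 = thresholds
    if not (t1 < t2 < t3):
        raise ValueError("thresholds must be strictly ascending")
    if corrected < 0:
        raise ValueError("corrected intensity must be >= 0")
    if corrected < t1:
        return 0
    if corrected < t2:
        return 2
    if corrected < t3:
        return 4
    return 6


def ihc_score(grades: Sequence[CellGrade | int]) -> IhcScore:
    """Composite slide score: percentage positivity × modal intensity.

    The modal intensity is the most frequent grade among positive cells;
    a tie is broken toward the higher grade.  An all-negative slide scores
    zero.
    """
    g = [x.intensity_grade if isinstance(x, CellGrade) else int(x) for x in grades]
    if not g:
        raise ValueError("need at least one graded cell")
    positive = [x for x in g if x > 0]
    pct = 100.0 * len(positive) / len(g)
    if not positive:
        return IhcScore(percent_positive=0.0, modal_intensity=0, final_score=0.0)
    counts = {grade: positive.count(grade) for grade in (2, 4, 6)}
    modal = max((2, 4, 6), key=lambda grade: (counts[grade], grade))
    return IhcScore(percent_positive=pct, modal_intensity=modal,
                    final_score=pct * modal)


def marker_features(
    cells_by_marker: dict[str, Sequence[CellGrade]],
) -> MarkerFeatureSet:
    """Patient-level marker feature set from per-cell grades.

    ``cells_by_marker`` maps marker names (SNA1, CD44, CYCD1, MAA) to the
    graded cells measured on that channel.  Absent markers stay ``None``
    (missing, not zero).  CD44pct counts cells strictly above grade 4.
    """
    fs = MarkerFeatureSet()

    def grades(marker):
        cells = cells_by_marker.get(marker)
        if not cells:
            return None
        return [c.intensity_grade for c in cells]

    def npos_pct(marker):
        cells = cells_by_marker.get(marker)
        if not cells:
            return None
        return 100.0 * sum(c.nuclear_positive for c in cells) / len(cells)

    sna = grades("SNA1")
    if sna is not None:
        fs.SNA1avg = float(np.mean(sna))
        fs.SNA1max = float(np.max(sna))
    cd44 = grades("CD44")
    if cd44 is not None:
        fs.CD44max = float(np.max(cd44))
        fs.CD44pct = 100.0 * sum(g > 4 for g in cd44) / len(cd44)
        fs.CD44Npos = npos_pct("CD44")
    if grades("CYCD1") is not None:
        fs.CYCD1Npos = npos_pct("CYCD1")
    maa = grades("MAA")
    if maa is not None:
        fs.MAAavg = float(np.mean(maa))
    return fs


def age_group(age: float) -> str:
    return AGE_GROUPS[0] if age <= 40 else AGE_GROUPS[1]


@dataclass
class NomogramTable:
    """Healthy-baseline reference table per site × age group.

    ``table`` is indexed by (site, age_group) and holds per-marker mean,
    SD and upper reference bound (mean + 2·SD).  Strata with fewer than
    two samples are flagged incomplete and carry no bound.
    """

    table: pd.DataFrame
    incomplete: list[tuple[str, str]] = field(default_factory=list)

    def bound(self, site: str, age_grp: str, marker: str) -> float:
        return float(self.table.loc[(site, age_grp), f"{marker}_upper"])


def build_nomogram(samples: pd.DataFrame, markers: Sequence[str] | None = None) -> NomogramTable:
    """Site- and age-stratified healthy baselines.

    ``samples`` carries one row per healthy sample with ``site``, ``age``
    (or ``age_group``) and marker feature columns.  Each stratum yields
    mean, SD (population) and mean + 2·SD per marker.
    """
    df = samples.copy()
    if "age_group" not in df.columns:
        df["age_group"] = df["age"].map(age_group)
    if markers is None:
        markers = [c for c in df.columns
                   if c not in ("site", "age", "age_group", "patient_id", "label")]
    rows, incomplete = {}, []
    for site in SITES:
        for grp in AGE_GROUPS:
            sub = df[(df["site"] == site) & (df["age_group"] == grp)]
            row = {}
            if len(sub) < 2:
                incomplete.append((site, grp))
            for m in markers:
                if len(sub) == 0:
                    row[f"{m}_mean"] = row[f"{m}_sd"] = row[f"{m}_upper"] = float("nan")
                    continue
                mean = float(sub[m].mean())
                sd = float(sub[m].std(ddof=0)) if len(sub) > 1 else float("nan")
                row[f"{m}_mean"] = mean
                row[f"{m}_sd"] = sd
                row[f"{m}_upper"] = mean + 2 * sd if len(sub) > 1 else float("nan")
            rows[(site, grp)] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["site", "age_group"])
    return NomogramTable(table=table, incomplete=incomplete)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float, float]:
    """Empirical ROC: (AUC, Youden-optimal cutoff, sensitivity, specificity).

    AUC by the trapezoid rule over the empirical curve (equals the
    Mann–Whitney concordance statistic).  The cutoff maximises Youden's
    J = sens + spec − 1; ties break toward the lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best_j = j.max()
    # roc_curve thresholds descend; ties toward the lower cutoff = last argmax
    best = int(np.flatnonzero(j == best_j)[-1])
    cutoff = float(thr[best])
    return auc, cutoff, float(tpr[best]), float(1.0 - fpr[best])
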