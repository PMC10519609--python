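"""Patient-level risk stratification (high-risk vs low-risk oral lesions).

Builds the statistical layer on top of per-patient feature vectors:
Kruskal–Wallis feature screening, variance-inflation-factor pruning,
several classifier families (plain logistic after VIF tuning, PCA +
L2-regularised logistic, random forest, RBF-SVM, gradient boosting),
3-fold cross-validated hyperparameter tuning on a stratified 70/30 split,
exact binomial confidence intervals for the reported proportions, and the
classical two-proportion sample-size formula.

The positive class throughout is HRL (high-grade dysplasia + carcinoma);
LRL is the negative class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

HRL_CLASSES = ("HGD", "OSCC")

__all__ = [
    "ModelSpec",
    "ModelReport",
    "SampleSizeSpec",
    "RiskStratifier",
    "kruskal_wallis",
    "vif_prune",
    "stratified_split",
    "fit_and_evaluate",
    "clopper_pearson",
    "sample_size_two_props",
]


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and its chi-square p-value.

    Degenerate input where every observation is identical gives H=0, p=1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def vif_prune(
    X: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the highest-VIF feature while any VIF > threshold.

    VIF_j = 1/(1−R²_j) from regressing feature j (with intercept) on the
    remaining features.  Perfectly collinear features surface as +inf and
    are dropped first.  Returns the retained feature names and a trace
    table (round, feature, vif, dropped).
    """
    cols = list(X.columns)
    trace_rows = []
    round_no = 0
    while len(cols) > 1:
        vifs = {}
        for j, col in enumerate(cols):
            yj = X[col].to_numpy(dtype=float)
            others = X[[c for c in cols if c != col]].to_numpy(dtype=float)
            A = np.column_stack([np.ones(len(yj)), others])
            coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
            resid = yj - A @ coef
            ss_res = float(resid @ resid)
            ss_tot = float(np.sum((yj - yj.mean()) ** 2))
            if ss_tot <= 0:
                vifs[col] = np.inf  # constant column
                continue
            r2 = 1.0 - ss_res / ss_tot
            vifs[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(vifs, key=lambda c: vifs[c])
        drop = vifs[worst] > threshold
        for col in cols:
            trace_rows.append({
                "round": round_no, "feature": col, "vif": vifs[col],
                "dropped": drop and col == worst,
            })
        if not drop:
            break
        cols.remove(worst)
        round_no += 1
    return cols, pd.DataFrame(trace_rows)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    y: np.ndarray, test_fraction: float = 0.30, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split with round-half-up per-class test counts.

    With 79 positives / 55 negatives and test_fraction 0.30 this yields a
    24/17 test composition (23.7 -> 24, 16.5 -> 17).
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_test = _round_half_up(len(idx) * test_fraction)
        n_test = min(max(n_test, 1), len(idx) - 1)
        test_idx.append(rng.permutation(idx)[:n_test])
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    return train_idx, test_idx


@dataclass
class ModelSpec:
    """Which classifier family to fit and how to tune it."""

    kind: str = "logistic_vif"  # logistic_vif | pca_l2_logistic | random_forest | svm | gradient_boosting
    cv_folds: int = 3
    test_fraction: float = 0.30
    vif_threshold: float = 10.0
    screen_alpha: float = 0.05  # per-feature Kruskal-Wallis screen; None disables
    param_grid: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class ModelReport:
    kind: str
    selected_features: list[str]
    feature_p_values: dict[str, float]
    vif_trace: pd.DataFrame | None
    best_params: dict
    # confusion counts on the held-out test set (positive = HRL)
    tp: int
    fp: int
    tn: int
    fn: int
    train_metrics: dict[str, float]
    test_metrics: dict[str, float]
    ci: dict[str, tuple[float, float]]  # percent-scale 95% exact CIs

    def recompute_test_metrics(self) -> dict[str, float]:
        """Metrics recomputed from the stored confusion counts."""
        n = self.tp + self.fp + self.tn + self.fn
        return {
            "sensitivity": self.tp / (self.tp + self.fn),
            "specificity": self.tn / (self.tn + self.fp),
            "accuracy": (self.tp + self.tn) / n,
        }


class RiskStratifier(BaseEstimator, ClassifierMixin):
    """Two-class lesion-risk classifier over patient feature vectors.

    A scikit-learn estimator wrapping the model families used for
    HRL-vs-LRL stratification.  ``kind='logistic_vif'`` first screens
    features by Kruskal–Wallis p-value and prunes collinear ones by VIF,
    then fits an unpenalised logistic regression; the other kinds tune
    their hyperparameter grid by stratified k-fold CV.  Standardisation is
    always fit on the training data only.

    Parameters
    ----------
    kind : model family (see :class:`ModelSpec`).
    cv_folds : folds for the inner grid search (default 3).
    vif_threshold : VIF above which a feature is pruned (default 10).
    screen_alpha : Kruskal–Wallis screening level; ``None`` disables.
    param_grid : overrides the built-in hyperparameter grid.
    random_state : seed for CV shuffling and stochastic learners.
    """

    def __init__(self, kind: str = "logistic_vif", cv_folds: int = 3,
                 vif_threshold: float = 10.0, screen_alpha: float | None = 0.05,
                 param_grid: dict | None = None, random_state: int = 0):
        self.kind = kind
        self.cv_folds = cv_folds
        self.vif_threshold = vif_threshold
        self.screen_alpha = screen_alpha
        self.param_grid = param_grid
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _base_pipeline(self) -> tuple[Pipeline, dict]:
        rs = self.random_state
        if self.kind in ("logistic_vif",):
            est = LogisticRegression(C=np.inf, max_iter=2000)  # unpenalised
            grid = {}
        elif self.kind == "pca_l2_logistic":
            est = Pipeline([
                ("pca", PCA(random_state=rs)),
                ("clf", LogisticRegression(max_iter=2000)),  # default L2
            ])
            grid = {"est__pca__n_components": [2, 5, 10],
                    "est__clf__C": [0.1, 0.5, 1.0, 2.0]}
        elif self.kind == "random_forest":
            est = RandomForestClassifier(n_estimators=500, random_state=rs)
            grid = {"est__max_depth": [3, 5, None],
                    "est__max_features": ["sqrt", 0.5]}
        elif self.kind == "svm":
            est = SVC(kernel="rbf", probability=True, random_state=rs)
            grid = {"est__C": [0.5, 1.0, 5.0], "est__gamma": ["scale", 0.1]}
        elif self.kind == "gradient_boosting":
            est = GradientBoostingClassifier(random_state=rs)
            grid = {"est__max_depth": [2, 3], "est__learning_rate": [0.05, 0.1]}
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        pipe = Pipeline([("scale", StandardScaler()), ("est", est)])
        return pipe, (self.param_grid if self.param_grid is not None else grid)

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        X = pd.DataFrame(X).copy()
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("RiskStratifier is a two-class model")
        self.classes_ = classes
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)

        cols = list(X.columns)
        self.feature_p_values_ = {}
        if self.screen_alpha is not None:
            kept = []
            for col in cols:
                groups = [X[col].to_numpy()[y == c] for c in classes]
                _, p = kruskal_wallis(groups)
                self.feature_p_values_[col] = p
                if p < self.screen_alpha:
                    kept.append(col)
            cols = kept if kept else cols  # never screen away everything

        self.vif_trace_ = None
        if self.kind == "logistic_vif" and len(cols) > 1:
            # prune on standardised features so scale does not drive VIF
            Xs = pd.DataFrame(StandardScaler().fit_transform(X[cols]), columns=cols)
            cols, self.vif_trace_ = vif_prune(Xs, self.vif_threshold)
        self.selected_features_ = cols

        pipe, grid = self._base_pipeline()
        y01 = (y == classes[1]).astype(int)
        if grid:
            search = GridSearchCV(pipe, grid, cv=self.cv_folds, scoring="roc_auc")
            search.fit(X[cols].to_numpy(), y01)
            self.best_params_ = search.best_params_
            self.model_ = search.best_estimator_
        else:
            self.best_params_ = {}
            self.model_ = pipe.fit(X[cols].to_numpy(), y01)
        return self

    def _subset(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        return X[self.selected_features_].to_numpy()

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._subset(X))

    def predict(self, X):
        check_is_fitted(self, "model_")
        idx = self.model_.predict(self._subset(X))
        return self.classes_[idx]

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the positive (second) class."""
        return self.predict_proba(X)[:, 1]


def encode_cohort(df: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Encode a patient table into (numeric features, HRL/LRL labels)."""
    y = np.where(df["label"].isin(HRL_CLASSES), "HRL", "LRL")
    feats = df.drop(columns=["label", "patient_id"], errors="ignore").copy()
    if "site" in feats.columns:
        feats = pd.get_dummies(feats, columns=["site"], dtype=float)
    if "habit" in feats.columns:
        feats["habit"] = feats["habit"].astype(float)
    return feats.astype(float), y


def _binary_metrics(y_true01, y_pred01, scores) -> tuple[dict, tuple[int, int, int, int]]:
    tp = int(np.sum((y_true01 == 1) & (y_pred01 == 1)))
    fp = int(np.sum((y_true01 == 0) & (y_pred01 == 1)))
    tn = int(np.sum((y_true01 == 0) & (y_pred01 == 0)))
    fn = int(np.sum((y_true01 == 1) & (y_pred01 == 0)))
    m = {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / len(y_true01),
        "auc": float(roc_auc_score(y_true01, scores)),
    }
    return m, (tp, fp, tn, fn)


def _auc_ci(auc: float, n1: int, n2: int) -> tuple[float, float]:
    """Hanley–McNeil normal-approximation CI for an AUC, percent scale."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    se = math.sqrt(max(var, 0.0))
    return (max(0.0, auc - 1.959964 * se) * 100, min(1.0, auc + 1.959964 * se) * 100)


def fit_and_evaluate(cohort: pd.DataFrame, spec: ModelSpec) -> ModelReport:
    """Stratified 70/30 evaluation of one model family on a patient cohort.

    The cohort table carries the marker features, clinical covariates and a
    ``label`` column (LRL/HGD/OSCC or LRL/HRL).  HGD+OSCC form the positive
    HRL class.  The split is seeded and stratified with round-half-up
    per-class test counts; scaling and tuning happen on the training side
    only.  Reported sensitivity/specificity/accuracy come with exact
    Clopper–Pearson 95% CIs, the AUC with a Hanley–McNeil interval.
    """
    feats, y = encode_cohort(cohort)
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both HRL and LRL patients")
    train_idx, test_idx = stratified_split(y, spec.test_fraction, spec.seed)

    clf = RiskStratifier(
        kind=spec.kind, cv_folds=spec.cv_folds,
        vif_threshold=spec.vif_threshold, screen_alpha=spec.screen_alpha,
        param_grid=spec.param_grid, random_state=spec.seed,
    )
    clf.fit(feats.iloc[train_idx], y[train_idx])

    pos = "HRL"  # classes_ sorted -> ('HRL', 'LRL'); positive-class scores:
    pos_col = int(np.where(clf.classes_ == pos)[0][0])

    def eval_split(idx):
        y01 = (y[idx] == pos).astype(int)
        scores = clf.predict_proba(feats.iloc[idx])[:, pos_col]
        pred01 = (scores > 0.5).astype(int)
        return _binary_metrics(y01, pred01, scores)

    train_metrics, _ = eval_split(train_idx)
    test_metrics, (tp, fp, tn, fn) = eval_split(test_idx)

    ci = {
        "sensitivity": clopper_pearson(tp, tp + fn),
        "specificity": clopper_pearson(tn, tn + fp),
        "accuracy": clopper_pearson(tp + tn, tp + fp + tn + fn),
        "auc": _auc_ci(test_metrics["auc"], tp + fn, tn + fp),
    }
    return ModelReport(
        kind=spec.kind,
        selected_features=list(clf.selected_features_),
        feature_p_values=dict(clf.feature_p_values_),
        vif_trace=clf.vif_trace_,
        best_params=dict(clf.best_params_),
        tp=tp, fp=fp, tn=tn, fn=fn,
        train_metrics=train_metrics, test_metrics=test_metrics, ci=ci,
    )


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial CI on the percent scale.

    Beta-quantile form: low = B(α/2; k, n−k+1), high = B(1−α/2; k+1, n−k),
    with low=0 at k=0 and high=100 at k=n.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n, n >= 1")
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 100.0 if k == n else 100.0 * float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (low * 100.0 if k > 0 else 0.0, high)


@dataclass(frozen=True)
class SampleSizeSpec:
    p1: float
    p2: float
    power: float = 0.80
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for x in (self.p1, self.p2, self.power, self.alpha):
            if not 0.0 < x < 1.0:
                raise ValueError("all spec values must lie in (0, 1)")
        if self.p1 == self.p2:
            raise ValueError("p1 must differ from p2")


def sample_size_two_props(spec: SampleSizeSpec) -> int:
    """Per-group n for a two-sided two-proportion comparison.

    n = ceil[(z_{1−α/2}·√(2·p̄(1−p̄)) + z_{1−β}·√(p1(1−p1)+p2(1−p2)))² / (p1−p2)²]
    with p̄ the mean of the two proportions.
    """
    p1, p2 = spec.p1, spec.p2
    pbar = 0.5 * (p1 + p2)
    za = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    zb = stats.norm.ppf(spec.power)
    num = (za * math.sqrt(2.0 * pbar * (1.0 - pbar))
           + zb * math.sqrt(p1 * (1.0 - p1) + p2 * (1.0 - p2))) ** 2
    return int(math.ceil(num / (p1 - p2) ** 2))
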