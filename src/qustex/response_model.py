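"""Response-classification protocol.

Balanced subsampling of an imbalanced cohort into seven subsets, sequential
forward selection of at most three features, FLD / KNN / RBF-SVM scorers,
leave-one-out cross-validation, and the standard evaluation panel
(sensitivity, specificity, PPV, NPV, accuracy, AUC).

The *positive* class is the non-responder ("NR") minority, so sensitivity
is the fraction of non-responders caught.  Standardization and feature
selection are computed from training folds only (no leakage); a
"per_subset" legacy mode that selects once per subset before LOOCV is
provided for comparison and recorded in every report.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

POSITIVE_LABEL = "NR"
NEGATIVE_LABEL = "R"


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Patient table: unique ids, binary labels, named feature columns."""

    df: pd.DataFrame
    id_column: str = "id"
    label_column: str = "label"

    def __post_init__(self) -> None:
        if self.id_column not in self.df.columns or self.label_column not in self.df.columns:
            raise ValueError("cohort table needs id and label columns")
        if self.df[self.id_column].duplicated().any():
            raise ValueError("patient ids must be unique")
        labels = set(self.df[self.label_column].unique())
        if not labels <= {POSITIVE_LABEL, NEGATIVE_LABEL}:
            raise ValueError(f"labels must be in {{R, NR}}, got {labels}")

    @property
    def feature_columns(self) -> list[str]:
        return [
            c for c in self.df.columns if c not in (self.id_column, self.label_column)
        ]

    @property
    def n(self) -> int:
        return len(self.df)

    def X(self, features: Sequence[str] | None = None) -> np.ndarray:
        cols = list(features) if features is not None else self.feature_columns
        return self.df[cols].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        return (self.df[self.label_column] == POSITIVE_LABEL).to_numpy(dtype=int)

    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive)."""
        y = self.y()
        return int((y == 0).sum()), int((y == 1).sum())

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# classifiers (continuous scorers; higher score = more NR-like)
# ---------------------------------------------------------------------------


class _Standardizer:
    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_


class FLDClassifier:
    """Fisher's linear discriminant: w ~ Sw^-1 (mu1 - mu0), midpoint threshold."""

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    threshold = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FLDClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("FLD needs both classes in training data")
        self.scaler_ = _Standardizer().fit(X)
        Z = self.scaler_.transform(X)
        mu0 = Z[y == 0].mean(axis=0)
        mu1 = Z[y == 1].mean(axis=0)
        n = Z.shape[0]
        Sw = np.zeros((Z.shape[1], Z.shape[1]))
        for cls, mu in ((0, mu0), (1, mu1)):
            D = Z[y == cls] - mu
            Sw += D.T @ D
        Sw /= max(n - 2, 1)
        # ridge fallback keeps the solve well posed when Sw is singular
        Sw += self.ridge * np.trace(Sw) / max(Sw.shape[0], 1) * np.eye(Sw.shape[0])
        Sw += 1e-12 * np.eye(Sw.shape[0])
        self.w_ = np.linalg.solve(Sw, mu1 - mu0)
        self.offset_ = float(self.w_ @ (mu0 + mu1) / 2.0)
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler_.transform(np.asarray(X, dtype=float))
        return Z @ self.w_ - self.offset_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score_samples(X) > self.threshold).astype(int)


class KNNClassifier:
    """k-nearest-neighbors vote; score = fraction of NR neighbors."""

    def __init__(self, k: int = 5):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    threshold = 0.5

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNClassifier":
        X = np.asarray(X, dtype=float)
        if self.k > X.shape[0]:
            raise ValueError(
                f"k={self.k} exceeds training-set size {X.shape[0]}"
            )
        self.scaler_ = _Standardizer().fit(X)
        self.Z_ = self.scaler_.transform(X)
        self.y_ = np.asarray(y, dtype=int)
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler_.transform(np.asarray(X, dtype=float))
        d2 = ((Z[:, None, :] - self.Z_[None, :, :]) ** 2).sum(axis=2)
        # stable tie-break: argsort is deterministic on equal distances
        nearest = np.argsort(d2, axis=1, kind="stable")[:, : self.k]
        return self.y_[nearest].mean(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score_samples(X) > self.threshold).astype(int)


class SVMRBFClassifier:
    """RBF-kernel SVM (maximum margin); score = signed margin distance."""

    def __init__(self, C: float = 1.0, gamma: float | str = "scale"):
        self.C = C
        self.gamma = gamma

    threshold = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMRBFClassifier":
        X = np.asarray(X, dtype=float)
        self.scaler_ = _Standardizer().fit(X)
        self.svc_ = SVC(kernel="rbf", C=self.C, gamma=self.gamma)
        self.svc_.fit(self.scaler_.transform(X), np.asarray(y, dtype=int))
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        return self.svc_.decision_function(
            self.scaler_.transform(np.asarray(X, dtype=float))
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score_samples(X) > self.threshold).astype(int)


def train_fld(X: np.ndarray, y: np.ndarray) -> FLDClassifier:
    return FLDClassifier().fit(X, y)


def train_knn(X: np.ndarray, y: np.ndarray, k: int = 5) -> KNNClassifier:
    return KNNClassifier(k=k).fit(X, y)


def train_svm_rbf(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, gamma: float | str = "scale"
) -> SVMRBFClassifier:
    return SVMRBFClassifier(C=C, gamma=gamma).fit(X, y)


def classifier_factory(name: str, **params) -> Callable[[], object]:
    """'fld' | 'knn' | 'svm' -> zero-argument constructor of an unfit scorer."""
    name = name.lower()
    if name == "fld":
        return lambda: FLDClassifier(**params)
    if name == "knn":
        return lambda: KNNClassifier(**params)
    if name == "svm":
        return lambda: SVMRBFClassifier(**params)
    raise ValueError(f"unknown classifier {name!r}")


# ---------------------------------------------------------------------------
# balanced subsampling
# ---------------------------------------------------------------------------


def balanced_subsets(
    cohort: CohortTable, n_subsets: int = 7, seed: int = 0
) -> list[CohortTable]:
    """Class-balanced subsets: all minority members plus an equal-size random
    majority draw (without replacement within each subset)."""
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    y = cohort.y()
    n0, n1 = cohort.class_counts()
    if min(n0, n1) < 2:
        raise ValueError("minority class must have >= 2 members")
    minority = 1 if n1 <= n0 else 0
    min_idx = np.nonzero(y == minority)[0]
    maj_idx = np.nonzero(y != minority)[0]
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(n_subsets):
        draw = rng.choice(maj_idx, size=len(min_idx), replace=False)
        idx = np.sort(np.concatenate([min_idx, draw]))
        subsets.append(
            CohortTable(
                cohort.df.iloc[idx].reset_index(drop=True),
                cohort.id_column,
                cohort.label_column,
            )
        )
    return subsets


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve_points(scores: np.ndarray, y: np.ndarray) -> ROCCurve:
    """ROC by sweeping a threshold over the pooled continuous scores.

    Tied scores are grouped (diagonal segments), so the trapezoid AUC equals
    the Mann-Whitney U statistic / (n1 * n0) with the usual tie correction.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both classes")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cuts = np.concatenate([distinct, [len(s_sorted) - 1]])
    tp = np.cumsum(y_sorted)[cuts]
    fp = np.cumsum(1 - y_sorted)[cuts]
    tpr = np.concatenate([[0.0], tp / n1, [1.0]])
    fpr = np.concatenate([[0.0], fp / n0, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# forward selection + LOOCV
# ---------------------------------------------------------------------------


def _loocv_scores(
    X: np.ndarray, y: np.ndarray, factory: Callable[[], object]
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out score and prediction per left-out sample; single-class
    training folds are skipped (NaN score)."""
    n = len(y)
    scores = np.full(n, np.nan)
    preds = np.full(n, -1)
    for i in range(n):
        keep = np.arange(n) != i
        if len(np.unique(y[keep])) < 2:
            continue
        clf = factory()
        try:
            clf.fit(X[keep], y[keep])
        except ValueError:
            continue
        scores[i] = clf.score_samples(X[i : i + 1])[0]
        preds[i] = clf.predict(X[i : i + 1])[0]
    return scores, preds


def _loocv_accuracy(
    X: np.ndarray, y: np.ndarray, factory: Callable[[], object]
) -> float:
    _, preds = _loocv_scores(X, y, factory)
    ok = preds >= 0
    if not ok.any():
        return 0.0
    return float((preds[ok] == y[ok]).mean())


def forward_select(
    X: np.ndarray,
    y: np.ndarray,
    factory: Callable[[], object],
    candidate_features: Sequence[str],
    max_k: int = 3,
) -> list[str]:
    """Greedy sequential forward selection maximizing LOOCV accuracy.

    Stops early when no addition strictly improves the objective; ties are
    broken by candidate order (canonical feature order upstream).
    """
    if len(candidate_features) < 1:
        raise ValueError("need at least one candidate feature")
    X = np.asarray(X, dtype=float)
    names = list(candidate_features)
    col = {name: i for i, name in enumerate(names)}
    selected: list[str] = []
    best_acc = -np.inf
    while len(selected) < max_k:
        best_feature = None
        best_candidate_acc = best_acc
        for name in names:
            if name in selected:
                continue
            cols = [col[f] for f in selected + [name]]
            sub = X[:, cols]
            if np.allclose(sub[:, -1].std(), 0.0):
                continue  # degenerate candidate
            acc = _loocv_accuracy(sub, y, factory)
            if acc > best_candidate_acc:
                best_candidate_acc = acc
                best_feature = name
        if best_feature is None:
            break
        selected.append(best_feature)
        best_acc = best_candidate_acc
    return selected


@dataclass
class EvalResult:
    """Evaluation panel for one subset or an aggregate."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    auc: float
    selected_features: list[str] = field(default_factory=list)
    selection_mode: str = "nested"
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None
    roc: ROCCurve | None = None
    per_subset: list["EvalResult"] = field(default_factory=list)

    def panel(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "auc": self.auc,
        }


def _confusion_panel(preds: np.ndarray, y: np.ndarray) -> dict[str, float]:
    tp = int(((preds == 1) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())

    def _ratio(a: int, b: int) -> float:
        return a / b if b else float("nan")

    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "accuracy": _ratio(tp + tn, tp + tn + fp + fn),
    }


def loocv_evaluate(
    subset: CohortTable,
    factory: Callable[[], object],
    candidate_features: Sequence[str] | None = None,
    selection_policy: str = "nested",
    max_features: int = 3,
) -> EvalResult:
    """Leave-one-out evaluation of one balanced subset.

    ``selection_policy``:
      * ``"nested"`` (default): features re-selected inside every training
        fold — unbiased;
      * ``"per_subset"``: selected once on the whole subset before LOOCV
        (legacy, optimistic);
      * ``"none"``: use all candidates, no selection.
    """
    if selection_policy not in ("nested", "per_subset", "none"):
        raise ValueError(f"unknown selection_policy {selection_policy!r}")
    features = list(
        candidate_features if candidate_features is not None else subset.feature_columns
    )
    Xall = subset.X(features)
    y = subset.y()
    n = len(y)
    col = {name: i for i, name in enumerate(features)}

    fixed: list[str] | None = None
    if selection_policy == "per_subset":
        fixed = forward_select(Xall, y, factory, features, max_k=max_features)
    elif selection_policy == "none":
        fixed = features

    scores = np.full(n, np.nan)
    preds = np.full(n, -1)
    fold_selections: list[tuple[str, ...]] = []
    for i in range(n):
        keep = np.arange(n) != i
        if len(np.unique(y[keep])) < 2:
            continue
        if fixed is not None:
            sel = fixed
        else:
            sel = forward_select(
                Xall[keep], y[keep], factory, features, max_k=max_features
            )
            fold_selections.append(tuple(sel))
        if not sel:
            continue
        cols = [col[f] for f in sel]
        clf = factory()
        try:
            clf.fit(Xall[np.ix_(keep, cols)], y[keep])
        except ValueError:
            continue
        xi = Xall[i : i + 1, cols]
        scores[i] = clf.score_samples(xi)[0]
        preds[i] = clf.predict(xi)[0]

    ok = (preds >= 0) & np.isfinite(scores)
    if not ok.any():
        raise ValueError("no usable LOOCV folds")
    panel = _confusion_panel(preds[ok], y[ok])
    roc = roc_curve_points(scores[ok], y[ok])
    if fixed is not None:
        reported = list(fixed)
    else:
        # nested mode: report the modal selection across training folds
        counts = Counter(fold_selections)
        reported = list(counts.most_common(1)[0][0]) if counts else []
    return EvalResult(
        **panel,
        auc=roc.auc,
        selected_features=reported,
        selection_mode=selection_policy,
        scores=scores[ok],
        labels=y[ok],
        roc=roc,
    )


def aggregate_subsets(results: list[EvalResult], rule: str = "mean") -> EvalResult:
    """Combine per-subset panels: unweighted metric mean (default) or a
    pooled-score recomputation."""
    if not results:
        raise ValueError("need at least one subset result")
    if rule not in ("mean", "pooled"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    if rule == "mean":
        keys = ["sensitivity", "specificity", "ppv", "npv", "accuracy", "auc"]
        mean = {k: float(np.mean([getattr(r, k) for r in results])) for k in keys}
        roc = None
        scores = labels = None
    else:
        scores = np.concatenate([r.scores for r in results])
        labels = np.concatenate([r.labels for r in results])
        roc = roc_curve_points(scores, labels)
        thresh_preds = None  # thresholds differ per classifier; reuse panels
        keys = ["sensitivity", "specificity", "ppv", "npv", "accuracy"]
        mean = {k: float(np.mean([getattr(r, k) for r in results])) for k in keys}
        mean["auc"] = roc.auc
        del thresh_preds
    selected = sorted({f for r in results for f in r.selected_features})
    return EvalResult(
        **mean,
        selected_features=selected,
        selection_mode=results[0].selection_mode,
        scores=scores,
        labels=labels,
        roc=roc,
        per_subset=list(results),
    )


# ---------------------------------------------------------------------------
# univariate feature comparison
# ---------------------------------------------------------------------------


def compare_feature_distributions(
    cohort: CohortTable, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature two-group comparison with a normality gate.

    Shapiro-Wilk in both classes; p >= 0.05 in both routes the feature to an
    unpaired t-test, otherwise to a two-sided Mann-Whitney test.  Constant
    features are skipped and flagged.
    """
    y = cohort.y()
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise ValueError("both classes need >= 3 samples")
    rows = []
    for name in cohort.feature_columns:
        v = cohort.df[name].to_numpy(dtype=float)
        a, b = v[y == 1], v[y == 0]
        finite = np.isfinite(a).all() and np.isfinite(b).all()
        if not finite or np.ptp(v) == 0:
            rows.append(
                {"feature": name, "test": "skipped", "p_value": np.nan,
                 "significant": False, "skipped": True}
            )
            continue

        def _normal(x: np.ndarray) -> bool:
            if np.ptp(x) == 0:
                return False
            return stats.shapiro(x).pvalue >= 0.05

        if _normal(a) and _normal(b):
            test = "t"
            p = stats.ttest_ind(a, b).pvalue
        else:
            test = "mannwhitney"
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append(
            {"feature": name, "test": test, "p_value": float(p),
             "significant": bool(p < alpha), "skipped": False}
        )
    return pd.DataFrame(rows)
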