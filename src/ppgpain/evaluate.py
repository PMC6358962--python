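"""Subject-wise cross-validation, confusion/accuracy metrics, ROC/AUC and the
AUC-vs-chance t-test.

Subjects (never individual windows) are the unit of splitting: each fold
holds one of k near-equal subject groups out for testing and the next group
for validation, so a subject's windows never span roles. With 78 subjects and
k = 6 each fold trains on 52 subjects and validates/tests on 13 + 13 —
1040 / 260 / 260 five-minute windows for paired 14-minute recordings.

Accuracy is (TP + TN) / (TP + FP + FN + TN) * 100 (trace/total for
multiclass); the ROC curve comes from a threshold sweep with trapezoidal AUC
(equal to the normalized Mann-Whitney U statistic), and ensemble AUC
uncertainty is summarized by bootstrap resampling of the test scores with a
two-tailed one-sample t-test against the chance level 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

__all__ = ["SplitPlan", "EvalReport", "subject_kfold", "confusion_and_accuracy",
           "roc_auc", "bootstrap_auc", "auc_vs_half_ttest"]


@dataclass(frozen=True)
class FoldRoles:
    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]


@dataclass(frozen=True)
class SplitPlan:
    """Per-fold subject role assignment for subject-wise k-fold CV."""

    k: int
    folds: tuple[FoldRoles, ...]

    def __post_init__(self) -> None:
        all_subjects = set().union(*(set(f.train) | set(f.validation) | set(f.test)
                                     for f in self.folds))
        for f in self.folds:
            roles = [set(f.train), set(f.validation), set(f.test)]
            if roles[0] | roles[1] | roles[2] != all_subjects:
                raise ValueError("fold roles must partition the subjects")
            if (roles[0] & roles[1]) or (roles[0] & roles[2]) or (roles[1] & roles[2]):
                raise ValueError("a subject may hold only one role per fold")
        tested = [s for f in self.folds for s in f.test]
        if sorted(tested) != sorted(all_subjects):
            raise ValueError("every subject must be tested exactly once across folds")


def subject_kfold(subjects: list[str], k: int, seed: int = 0) -> SplitPlan:
    """Shuffle subjects into k near-equal groups; fold i tests group i,
    validates group i+1 (mod k) and trains on the rest."""
    subjects = list(subjects)
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the {len(subjects)} available subjects")
    if k < 3:
        raise ValueError("need k >= 3 for disjoint train/validation/test roles")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    groups = [sorted(subjects[i] for i in g) for g in np.array_split(order, k)]
    folds = []
    for i in range(k):
        test = groups[i]
        val = groups[(i + 1) % k]
        train = sorted(s for g in groups for s in g if s not in set(test) | set(val))
        folds.append(FoldRoles(tuple(train), tuple(val), tuple(test)))
    return SplitPlan(k=k, folds=tuple(folds))


@dataclass
class EvalReport:
    """Confusion counts, accuracy and (binary) sensitivity/specificity."""

    confusion: np.ndarray
    classes: np.ndarray
    accuracy: float
    sensitivity: float | None = None
    specificity: float | None = None
    auc: float | None = None
    auc_sd: float | None = None
    auc_ci: tuple[float, float] | None = None
    auc_p_vs_chance: float | None = None
    roc_points: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
        }
        for name in ("sensitivity", "specificity", "auc", "auc_sd", "auc_p_vs_chance"):
            val = getattr(self, name)
            if val is not None:
                out[name] = float(val)
        if self.auc_ci is not None:
            out["auc_ci"] = [float(v) for v in self.auc_ci]
        return out


def confusion_and_accuracy(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    positive: object = "P",
) -> EvalReport:
    """Confusion matrix and accuracy = (TP+TN)/total * 100.

    Binary inputs additionally yield sensitivity TP/(TP+FN) and specificity
    TN/(TN+FP) with ``positive`` as the positive class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("label vectors must be non-empty and equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    cm = skm.confusion_matrix(y_true, y_pred, labels=classes)
    accuracy = 100.0 * float(np.trace(cm)) / float(cm.sum())

    sens = spec = None
    if classes.size == 2:
        pos = int(np.flatnonzero(classes == positive)[0]) if positive in classes else 1
        neg = 1 - pos
        tp, fn = cm[pos, pos], cm[pos, neg]
        tn, fp = cm[neg, neg], cm[neg, pos]
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
    return EvalReport(confusion=cm, classes=classes, accuracy=accuracy,
                      sensitivity=sens, specificity=spec)


def roc_auc(
    scores: np.ndarray, y_true: np.ndarray, positive: object = "P"
) -> tuple[pd.DataFrame, float]:
    """ROC points (threshold sweep) and trapezoidal AUC for binary labels."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(y_true)
    if classes.size != 2:
        raise ValueError(f"ROC analysis needs both classes present, got {classes}")
    y_bin = (y_true == positive).astype(int)
    fpr, tpr, thr = skm.roc_curve(y_bin, scores)
    auc = float(skm.auc(fpr, tpr))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, auc


def bootstrap_auc(
    scores: np.ndarray,
    y_true: np.ndarray,
    n_boot: int = 300,
    seed: int = 0,
    positive: object = "P",
) -> np.ndarray:
    """AUC over ``n_boot`` bootstrap resamples of the test scores."""
    rng = np.random.default_rng(seed)
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n = y_true.size
    out = []
    while len(out) < n_boot:
        idx = rng.integers(0, n, size=n)
        if np.unique(y_true[idx]).size < 2:
            continue  # resample until both classes are present
        out.append(roc_auc(scores[idx], y_true[idx], positive)[1])
    return np.asarray(out)


def auc_vs_half_ttest(auc_samples: np.ndarray) -> dict:
    """Two-tailed one-sample t-test of AUC samples against chance (0.5).

    Returns mean, sd, 95% CI of the samples and the p-value. Zero-variance
    samples take the degenerate branch: p = 1 when the common value is 0.5,
    otherwise p is reported at the floating-point floor.
    """
    a = np.asarray(auc_samples, dtype=float)
    if a.size < 2:
        raise ValueError("need >= 2 AUC samples")
    mean = float(a.mean())
    sd = float(a.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if mean == 0.5 else np.finfo(float).tiny
        ci = (mean, mean)
    else:
        t = stats.ttest_1samp(a, 0.5)
        p = float(t.pvalue)
        half = stats.t.ppf(0.975, a.size - 1) * sd / np.sqrt(a.size)
        ci = (mean - half, mean + half)
    return {"mean": mean, "sd": sd, "ci95": ci, "p_value": float(p), "n": int(a.size)}
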