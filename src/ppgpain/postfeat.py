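"""Feature-matrix post-processing: MAD outlier screening, min-max
normalization, and statistical feature screening.

Outlier rows are removed with the median-absolute-deviation rule: per feature
j, ``MAD_j = 1.4826 * median(|x_ij - median(x_j)|)`` and any row with a value
at or beyond ``median +/- k * MAD`` (k = 2.5) in any feature is dropped.
Features are then min-max normalized to [0, 1] with the transform fitted on
training rows only and clipped elsewhere. Screening keeps features whose
class difference is significant: a paired Wilcoxon signed-rank test
(subject/window-matched pre vs post) for the 2-class protocol, one-way ANOVA
across the four pain statuses for the 4-class protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

__all__ = ["mad_filter", "MinMaxNormalizer", "minmax_fit_apply", "screen_features"]

MAD_SCALE = 1.4826  # consistency factor with the SD under normality


def mad_filter(
    matrix: pd.DataFrame,
    k: float = 2.5,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows with any feature at or outside median +/- k*MAD.

    Features with MAD = 0 are skipped (logged via warning) rather than
    removing every off-median row. Returns the filtered matrix and a report
    frame (row index, triggering feature, value, lower/upper bound).
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 rows for a meaningful MAD screen")
    removed = []
    keep = np.ones(len(matrix), dtype=bool)
    for name in feature_names:
        col = matrix[name].to_numpy(dtype=float)
        med = float(np.median(col))
        mad = MAD_SCALE * float(np.median(np.abs(col - med)))
        if mad == 0.0:
            warnings.warn(f"feature {name!r} has zero MAD; skipped in outlier screen")
            continue
        lo, hi = med - k * mad, med + k * mad
        out = (col <= lo) | (col >= hi)
        for i in np.flatnonzero(out):
            removed.append({"row": matrix.index[i], "feature": name,
                            "value": col[i], "lower": lo, "upper": hi})
        keep &= ~out
    report = pd.DataFrame(removed, columns=["row", "feature", "value", "lower", "upper"])
    return matrix.loc[keep].copy(), report


@dataclass
class MinMaxNormalizer:
    """Per-feature min-max transform fitted on training rows.

    Non-training values map outside [0, 1] and are clipped; a constant
    training feature maps to 0 everywhere (with a warning at fit time).
    """

    feature_names: tuple[str, ...] = FEATURE_NAMES
    mins_: dict[str, float] = field(default_factory=dict)
    maxs_: dict[str, float] = field(default_factory=dict)

    def fit(self, train: pd.DataFrame) -> "MinMaxNormalizer":
        for name in self.feature_names:
            col = train[name].to_numpy(dtype=float)
            self.mins_[name] = float(np.min(col))
            self.maxs_[name] = float(np.max(col))
            if self.mins_[name] == self.maxs_[name]:
                warnings.warn(f"feature {name!r} is constant on the training rows; "
                              "it normalizes to 0")
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if not self.mins_:
            raise ValueError("normalizer has not been fitted")
        out = matrix.copy()
        for name in self.feature_names:
            lo, hi = self.mins_[name], self.maxs_[name]
            col = out[name].to_numpy(dtype=float)
            if hi == lo:
                out[name] = 0.0
            else:
                out[name] = np.clip((col - lo) / (hi - lo), 0.0, 1.0)
        return out


def minmax_fit_apply(
    train: pd.DataFrame,
    *others: pd.DataFrame,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> tuple[pd.DataFrame, ...]:
    """Fit min-max on ``train`` and apply to train plus any other matrices."""
    norm = MinMaxNormalizer(feature_names=feature_names).fit(train)
    return tuple(norm.transform(m) for m in (train, *others))


def screen_features(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    mode: str = "two_class",
    alpha: float = 0.05,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> tuple[list[str], pd.DataFrame]:
    """Keep features whose class difference is significant at ``alpha``.

    ``two_class``: paired Wilcoxon signed-rank per feature, pairing rows by
    (subject_id, window_index) across the two labels; subjects with an
    unpairable window are dropped from the test (warned). ``four_class``:
    one-way ANOVA across the label groups.

    Returns (retained feature names, report with feature/p_value/retained).
    """
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels))
    rows = []
    if mode == "two_class":
        if len(classes) != 2:
            raise ValueError(f"two_class screening needs exactly 2 labels, got {classes}")
        a = matrix.loc[labels == classes[0]].set_index(["subject_id", "window_index"])
        b = matrix.loc[labels == classes[1]].set_index(["subject_id", "window_index"])
        common = a.index.intersection(b.index)
        dropped = (len(a) - len(common)) + (len(b) - len(common))
        if dropped:
            warnings.warn(f"{dropped} unpairable rows dropped from the paired test")
        if len(common) < 5:
            raise ValueError("too few matched pre/post pairs for a paired test")
        for name in feature_names:
            d = a.loc[common, name].to_numpy(float) - b.loc[common, name].to_numpy(float)
            if np.allclose(d, 0.0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(d).pvalue)
            rows.append({"feature": name, "p_value": p, "retained": p < alpha})
    elif mode == "four_class":
        groups_idx = [labels == c for c in classes]
        if len(classes) < 2:
            raise ValueError("need >= 2 label groups for ANOVA")
        for name in feature_names:
            groups = [matrix.loc[g, name].to_numpy(float) for g in groups_idx]
            if all(np.ptp(g) == 0 for g in groups if g.size):
                p = 1.0
            else:
                p = float(stats.f_oneway(*groups).pvalue)
            rows.append({"feature": name, "p_value": p, "retained": p < alpha})
    else:
        raise ValueError(f"unknown screening mode {mode!r}")
    report = pd.DataFrame(rows)
    retained = report.loc[report["retained"], "feature"].tolist()
    return retained, report
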