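"""Per-date ANOVA screening of phenotypic features across N treatments.

Each feature is tested at every sampling date with a one-way ANOVA
across the treatment groups; a feature enters the selected set only if
its p-value is below alpha at *every* date.  For plotting, p-values are
transformed to -log10(p) against the threshold line -log10(alpha)
(1.301 at alpha = 0.05).  Features are z-scored beforehand (the scale
does not affect the F-test, but the standardized table is what the
downstream regressors consume).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .reference import preset_features

__all__ = [
    "ScreeningResult",
    "normalize_features",
    "anova_screen",
    "significance_plot_data",
    "AnovaScreener",
]

_P_FLOOR = 1e-300


@dataclass
class ScreeningResult:
    """Outcome of the per-date ANOVA screen."""

    p_matrix: pd.DataFrame      # features x dates
    alpha: float
    selected: list[str] = field(init=False)
    neglog10: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.selected = list(
            self.p_matrix.index[(self.p_matrix < self.alpha).all(axis=1)]
        )
        self.neglog10 = -np.log10(self.p_matrix.clip(lower=_P_FLOOR))


def normalize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score ((x - mean) / population std).

    Constant columns are mapped to zero with a warning.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    arr = table.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    std = arr.std(axis=0)
    constant = std == 0
    if constant.any():
        warnings.warn(
            f"constant features mapped to 0: {list(table.columns[constant])}"
        )
    std_safe = np.where(constant, 1.0, std)
    z = (arr - mean) / std_safe
    z[:, constant] = 0.0
    return pd.DataFrame(z, index=table.index, columns=table.columns)


def _anova_p_one_date(arr: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Vectorized one-way ANOVA p-values for every column of ``arr``.

    Degenerate columns (zero within-group variance) get p = 1 when the
    group means agree and p -> 0 (floored) when they differ.
    """
    blocks = [arr[g] for g in groups]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.f_oneway(*blocks, axis=0).pvalue
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        for j in np.where(bad)[0]:
            means = [b[:, j].mean() for b in blocks]
            within = sum(((b[:, j] - b[:, j].mean()) ** 2).sum() for b in blocks)
            if within == 0 and np.ptp(means) > 0:
                p[j] = _P_FLOOR
            else:
                p[j] = 1.0
    return np.clip(p, _P_FLOOR, 1.0)


def anova_screen(
    features: pd.DataFrame,
    treatments,
    days,
    alpha: float = 0.05,
) -> ScreeningResult:
    """Per-(feature, date) one-way ANOVA across treatments.

    ``features`` is a samples x features table; ``treatments`` and
    ``days`` are per-sample labels.  A feature is selected iff
    p < alpha (strict) at every date.
    """
    treatments = np.asarray(treatments)
    days = np.asarray(days)
    arr = features.to_numpy(dtype=float)
    p_cols = {}
    for day in sorted(pd.unique(days)):
        in_day = days == day
        trts = pd.unique(treatments[in_day])
        if len(trts) < 2:
            raise ValueError(f"day {day}: need >= 2 treatments")
        groups = []
        for trt in trts:
            idx = np.where(in_day & (treatments == trt))[0]
            if idx.size < 2:
                raise ValueError(f"day {day}, treatment {trt}: need >= 2 samples")
            groups.append(idx)
        p_cols[day] = _anova_p_one_date(arr, groups)
    p_matrix = pd.DataFrame(p_cols, index=features.columns)
    return ScreeningResult(p_matrix=p_matrix, alpha=alpha)


def significance_plot_data(result: ScreeningResult) -> dict:
    """Per-date points for a significance ("Manhattan-style") plot.

    Returns ``{"threshold": -log10(alpha), "dates": {day: [(feature_no,
    neglog10_p, significant), ...]}}`` with 1-based feature numbers and
    the strict rule p < alpha.
    """
    threshold = float(-np.log10(result.alpha))
    dates = {}
    for day in result.p_matrix.columns:
        pts = []
        for no, feat in enumerate(result.p_matrix.index, start=1):
            p = result.p_matrix.at[feat, day]
            pts.append((no, float(result.neglog10.at[feat, day]), bool(p < result.alpha)))
        dates[day] = pts
    return {"threshold": threshold, "dates": dates}


class AnovaScreener(BaseEstimator, TransformerMixin):
    """Feature selector applying the all-dates ANOVA rule.

    ``fit(X, y, days=...)`` with X a feature DataFrame, y the treatment
    labels and ``days`` the sampling-date labels.  Alternatively set
    ``preset`` to a named published feature set (e.g. ``"paper23"``) to
    bypass screening.  ``transform`` keeps the selected columns.
    """

    def __init__(self, alpha: float = 0.05, preset: str | None = None):
        self.alpha = alpha
        self.preset = preset

    def fit(self, X, y=None, days=None):
        if self.preset is not None:
            self.selected_ = preset_features(self.preset)
            self.result_ = None
            return self
        if y is None or days is None:
            raise ValueError("screening needs treatment labels y and days")
        self.result_ = anova_screen(X, y, days, alpha=self.alpha)
        self.selected_ = self.result_.selected
        return self

    def transform(self, X):
        missing = [f for f in self.selected_ if f not in X.columns]
        if missing:
            raise ValueError(f"missing selected features: {missing}")
        return X[self.selected_]

    def get_support(self):
        return list(self.selected_)
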