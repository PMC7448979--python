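"""Molecular-descriptor preprocessing.

Descriptor tables (rows = entities, columns = numeric descriptors) are
cleaned by four removal criteria applied in a fixed order:

1. drop descriptors with any missing value;
2. drop near-constant descriptors whose modal value covers more than 80 %
   of entities (values compared after rounding to 6 significant digits);
3. drop descriptors with relative standard deviation (sample sd / |mean|)
   below 0.05; descriptors with mean exactly zero and positive sd are kept,
   their RSD being unbounded;
4. greedily break descriptor pairs with |Pearson r| above 0.9, dropping the
   member of the worst pair with the larger mean absolute correlation to
   the surviving set (tie: the later column).

The :class:`DescriptorCleaner` estimator wraps the pipeline in the
scikit-learn fit/transform idiom so it can sit in a Pipeline and be fitted
on a training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

STAGES = ("missing", "dominant_value", "low_rsd", "correlated")


@dataclass
class PreprocessReport:
    """Audit trail: which descriptors each stage removed, and the survivors."""

    dropped: dict = field(default_factory=dict)
    kept: list = field(default_factory=list)
    stage_order: tuple = STAGES

    @property
    def n_dropped(self) -> int:
        return sum(len(v) for v in self.dropped.values())


def _check_frame(dm) -> pd.DataFrame:
    if not isinstance(dm, pd.DataFrame):
        raise TypeError("descriptor matrix must be a pandas DataFrame")
    if dm.columns.duplicated().any():
        raise ValueError("descriptor names must be unique")
    return dm


def round_sig(x: np.ndarray, digits: int = 6) -> np.ndarray:
    """Round to ``digits`` significant figures (0 stays 0)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = (x != 0) & np.isfinite(x)
    mag = np.floor(np.log10(np.abs(x[nz])))
    factor = 10.0 ** (digits - 1 - mag)
    out[nz] = np.round(x[nz] * factor) / factor
    out[~np.isfinite(x)] = x[~np.isfinite(x)]
    return out


def drop_missing(dm: pd.DataFrame):
    """Remove every descriptor column containing at least one missing value."""
    dm = _check_frame(dm)
    bad = [c for c in dm.columns if dm[c].isna().any()]
    return dm.drop(columns=bad), bad


def drop_dominant_value(dm: pd.DataFrame, max_mode_fraction: float = 0.80):
    """Remove columns whose modal value covers strictly more than the cutoff."""
    dm = _check_frame(dm)
    n = len(dm)
    bad = []
    for c in dm.columns:
        vals = round_sig(dm[c].to_numpy())
        _, counts = np.unique(vals, return_counts=True)
        if n and counts.max() / n > max_mode_fraction:
            bad.append(c)
    return dm.drop(columns=bad), bad


def drop_low_rsd(dm: pd.DataFrame, min_rsd: float = 0.05):
    """Remove columns with sample-sd / |mean| below ``min_rsd``.

    Columns with mean exactly zero are kept when their sd is positive (the
    RSD is unbounded there) and dropped when constant at zero.
    """
    dm = _check_frame(dm)
    bad = []
    for c in dm.columns:
        x = dm[c].to_numpy(dtype=float)
        mean = x.mean()
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        if mean == 0.0:
            if sd == 0.0:
                bad.append(c)
            continue
        if sd / abs(mean) < min_rsd:
            bad.append(c)
    return dm.drop(columns=bad), bad


def drop_correlated(dm: pd.DataFrame, max_abs_r: float = 0.9):
    """Greedy decorrelation: break the worst pair until all |r| <= cutoff.

    At each step the pair with the highest |Pearson r| above ``max_abs_r``
    is found and the member with the larger mean |r| against all surviving
    columns is dropped (tie: the later column in the current order), then
    correlations are re-examined on the survivors.
    """
    dm = _check_frame(dm)
    if len(dm) < 3:
        raise ValueError("correlation filter needs at least 3 rows")
    cols = list(dm.columns)
    if len(cols) < 2:
        return dm, []
    corr = dm.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    # constant columns give NaN correlations; treat as uncorrelated
    corr = np.nan_to_num(corr, nan=0.0)
    alive = list(range(len(cols)))
    dropped_idx = []
    while len(alive) > 1:
        sub = corr[np.ix_(alive, alive)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= max_abs_r:
            break
        mean_i = sub[i].sum() / (len(alive) - 1)
        mean_j = sub[j].sum() / (len(alive) - 1)
        # drop the more globally redundant member; tie -> later column
        victim = i if mean_i > mean_j else j
        if mean_i == mean_j:
            victim = max(i, j)
        dropped_idx.append(alive[victim])
        del alive[victim]
    bad = [cols[k] for k in sorted(dropped_idx)]
    return dm.drop(columns=bad), bad


def preprocess(
    dm: pd.DataFrame,
    max_mode_fraction: float = 0.80,
    min_rsd: float = 0.05,
    max_abs_r: float = 0.9,
):
    """Apply the four removal stages in order; returns (clean, report)."""
    report = PreprocessReport()
    out, report.dropped["missing"] = drop_missing(dm)
    out, report.dropped["dominant_value"] = drop_dominant_value(out, max_mode_fraction)
    out, report.dropped["low_rsd"] = drop_low_rsd(out, min_rsd)
    if out.shape[1] == 0:
        raise ValueError("no descriptors survive preprocessing")
    out, report.dropped["correlated"] = drop_correlated(out, max_abs_r)
    if out.shape[1] == 0:
        raise ValueError("no descriptors survive preprocessing")
    report.kept = list(out.columns)
    return out, report


class DescriptorCleaner(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping the four-stage descriptor filter.

    Fitting learns the surviving column set from the training table;
    ``transform`` projects any table onto those columns.

    Parameters
    ----------
    max_mode_fraction : float, default 0.80
        Modal-value share above which a column counts as near-constant.
    min_rsd : float, default 0.05
        Minimum relative standard deviation.
    max_abs_r : float, default 0.9
        Maximum tolerated absolute pairwise Pearson correlation.
    """

    def __init__(self, max_mode_fraction: float = 0.80, min_rsd: float = 0.05,
                 max_abs_r: float = 0.9):
        self.max_mode_fraction = max_mode_fraction
        self.min_rsd = min_rsd
        self.max_abs_r = max_abs_r

    def fit(self, X: pd.DataFrame, y=None):
        _, report = preprocess(
            X,
            max_mode_fraction=self.max_mode_fraction,
            min_rsd=self.min_rsd,
            max_abs_r=self.max_abs_r,
        )
        self.report_ = report
        self.kept_ = list(report.kept)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "kept_"):
            raise RuntimeError("DescriptorCleaner is not fitted")
        missing = [c for c in self.kept_ if c not in X.columns]
        if missing:
            raise ValueError(f"columns missing from input: {missing}")
        return X[self.kept_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.kept_, dtype=object)
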