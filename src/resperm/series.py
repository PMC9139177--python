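"""Ordered-series container and two-segment ordinary least squares.

The unit of detection is a :class:`Series`: an ordered regressor ``x``
(observation index, time, trial number ...), a numeric response ``y`` and
optional external per-observation labels (e.g. original experiment trial
numbers when the series itself is indexed by retained-observation number).

Both changepoint detectors in this package reduce to fitting two
independent simple linear regressions on the observations before and after
a candidate split; :func:`fit_segment_pair` is that shared primitive.  No
continuity constraint is imposed here — the segmented comparator adds its
own constraint in its working model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Series", "SegmentPairFit", "fit_segment_pair", "read_series_csv",
           "write_fit_json"]


@dataclass(frozen=True)
class Series:
    """An ordered (x, y) sample, the input of changepoint detection.

    Parameters
    ----------
    x : array-like of shape (n,)
        Strictly increasing regressor values. Detection requires an
        orderable regressor; ties are rejected.
    y : array-like of shape (n,)
        Response values, same length as ``x``.
    labels : array-like of shape (n,), optional
        External identifiers carried through to results (e.g. experiment
        trial numbers). Never used in fitting.

    Notes
    -----
    Missing values are rejected: callers must drop incomplete observations
    before construction.
    """

    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if x.size < 2:
            raise ValueError("a series needs at least 2 observations")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("x and y must be finite; drop incomplete "
                             "observations before constructing a Series")
        if not np.all(np.diff(x) > 0):
            raise ValueError("x must be strictly increasing")
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != x.shape:
                raise ValueError("labels must have the same length as x")
            object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class SegmentPairFit:
    """Two independent OLS lines split after observation ``k`` (1-based).

    Observations 1..k form regime 1, k+1..n regime 2; each regime gets its
    own intercept and slope, so the pair may be discontinuous at the split.
    ``fitted + residuals`` reconstructs ``y`` exactly and the residuals of
    each regime sum to zero (OLS with intercept).
    """

    k: int
    b01: float
    b11: float
    b02: float
    b12: float
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)


def _ols_line(x: np.ndarray, y: np.ndarray, which: str) -> tuple[float, float]:
    """Intercept and slope of a simple OLS line; errors on degenerate x."""
    xm = x.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError(f"degenerate {which}: all x values equal, "
                         "slope is not identifiable")
    slope = float((x - xm) @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * xm)
    return intercept, slope


def fit_segment_pair(series: Series, k: int) -> SegmentPairFit:
    """Fit independent OLS lines to observations 1..k and k+1..n.

    Parameters
    ----------
    series : Series
    k : int
        1-based split index; observation ``k`` belongs to regime 1.
        Requires ``2 <= k <= n - 2`` so each regime supports a line.

    Returns
    -------
    SegmentPairFit
    """
    n = series.n
    if not 2 <= k <= n - 2:
        raise ValueError(f"split index k={k} out of range [2, {n - 2}]")
    x, y = series.x, series.y
    b01, b11 = _ols_line(x[:k], y[:k], "regime 1")
    b02, b12 = _ols_line(x[k:], y[k:], "regime 2")
    fitted = np.empty(n)
    fitted[:k] = b01 + b11 * x[:k]
    fitted[k:] = b02 + b12 * x[k:]
    return SegmentPairFit(k=k, b01=b01, b11=b11, b02=b02, b12=b12,
                          fitted=fitted, residuals=y - fitted)


def read_series_csv(path) -> Series:
    """Read a series from CSV with columns ``x,y`` and optional ``label``."""
    df = pd.read_csv(path, comment="#")
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"series CSV must have columns x,y; missing {missing}")
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return Series(df["x"].to_numpy(float), df["y"].to_numpy(float), labels)


def write_fit_json(fit: SegmentPairFit, path) -> None:
    """Write a segment-pair fit as a JSON record."""
    rec = {"k": fit.k, "b01": fit.b01, "b11": fit.b11,
           "b02": fit.b02, "b12": fit.b12,
           "fitted": fit.fitted.tolist(), "residuals": fit.residuals.tolist()}
    with open(path, "w") as fh:
        json.dump(rec, fh)
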