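"""Segmented (broken-line) regression with a single breakpoint.

Implements the classic iterative linearization for a continuous
two-regime line: given a current breakpoint guess ``c``, fit by OLS the
working model

    y ~ 1 + x + (x - c) * I(x > c) - gamma * I(x > c),

whose gap coefficient ``gamma`` measures how far the current guess is
from a kink; the update ``c <- c + gamma / (b12 - b11)`` drives the gap
to zero.  Convergence gives a continuous broken line with a breakpoint
on the continuous x scale.  When the iteration stalls, diverges or the
breakpoint leaves the data range, bootstrap restarting (refitting on a
nonparametric resample to obtain a fresh starting value) attempts an
escape; if every attempt fails the fit reports failure rather than a
breakpoint — a real behaviour of flat or breakpoint-free objectives
that downstream code must handle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .series import Series

__all__ = ["SegmentedConfig", "SegmentedResult", "SegmentedRegression",
           "segmented_fit"]


@dataclass(frozen=True)
class SegmentedConfig:
    """Iteration controls for the broken-line fit.

    chp0 : initial breakpoint; ``None`` means the median of x.
    tol : convergence tolerance on successive breakpoint updates.
    max_iter : iteration cap per start.
    n_restarts : bootstrap-restarting attempts after a failed start.
    max_retries : whole-fit reruns with fresh bootstrap seeds before a
        failure is declared (used by callers that own a retry policy).
    seed : RNG seed for bootstrap resampling.
    """

    chp0: float | None = None
    tol: float = 1e-8
    max_iter: int = 30
    n_restarts: int = 10
    max_retries: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.tol <= 0 or self.n_restarts < 0:
            raise ValueError("need max_iter >= 1, tol > 0, n_restarts >= 0")


@dataclass(frozen=True)
class SegmentedResult:
    """A converged (or failed) broken-line fit.

    ``chp`` is continuous, not snapped to an observation; ``k_nearest``
    is the 1-based observation number closest to it, for comparison with
    grid-based detectors.  ``chp is None`` signals failure.
    """

    chp: float | None
    b0: float
    b11: float
    b12: float
    rss: float
    converged: bool
    n_iter: int
    k_nearest: int | None

    @property
    def failed(self) -> bool:
        return self.chp is None


def _fit_constrained(x: np.ndarray, y: np.ndarray, chp: float):
    """OLS fit of the continuous broken line with the kink fixed at chp."""
    above = x > chp
    X = np.column_stack([np.ones_like(x), x, (x - chp) * above])
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    rss = float(((y - fitted) ** 2).sum())
    b0, b11, delta = coef
    return float(b0), float(b11), float(b11 + delta), rss


def _iterate(x: np.ndarray, y: np.ndarray, chp0: float, tol: float,
             max_iter: int) -> tuple[float | None, int]:
    """One run of the working-model iteration from chp0.

    Returns (chp, n_iter); chp is None on non-convergence, a flat
    slope-change coefficient, or a breakpoint escaping (min x, max x).
    """
    lo, hi = float(x[0]), float(x[-1])
    chp = float(chp0)
    prev_chp, step = np.nan, np.nan
    for it in range(1, max_iter + 1):
        above = x > chp
        if above.sum() < 2 or (~above).sum() < 2:
            return None, it
        X = np.column_stack([np.ones_like(x), x, (x - chp) * above,
                             -above.astype(float)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        delta, gamma = coef[2], coef[3]
        if delta == 0 or not np.isfinite(gamma / delta):
            return None, it
        step = gamma / delta
        prev_chp = chp
        chp = chp + step
        if not lo < chp < hi:
            return None, it
        if abs(step) < tol:
            return chp, it
    # the iteration often ends in a 2-cycle straddling an optimum that
    # lies between observations; a sub-spacing oscillation counts as
    # converged, resolved in favour of the iterate with smaller RSS
    if np.isfinite(prev_chp) and abs(step) < 0.5 * (hi - lo) / (x.size - 1):
        pair = [(c, _fit_constrained(x, y, c)[3]) for c in (prev_chp, chp)]
        return min(pair, key=lambda t: t[1])[0], max_iter
    return None, max_iter


def segmented_fit(series: Series, config: SegmentedConfig | None = None
                  ) -> SegmentedResult:
    """Fit a continuous single-breakpoint line; functional front end."""
    config = config or SegmentedConfig()
    x, y = series.x, series.y
    if series.n < 6:
        raise ValueError("segmented fitting needs at least 6 observations")
    rng = np.random.default_rng(config.seed)
    chp0 = float(np.median(x)) if config.chp0 is None else float(config.chp0)

    best: SegmentedResult | None = None
    n_iter_total = 0

    def consider(chp: float | None, n_iter: int) -> None:
        nonlocal best
        if chp is None:
            return
        b0, b11, b12, rss = _fit_constrained(x, y, chp)
        k_nearest = int(np.argmin(np.abs(x - chp))) + 1
        cand = SegmentedResult(chp=chp, b0=b0, b11=b11, b12=b12, rss=rss,
                               converged=True, n_iter=n_iter,
                               k_nearest=k_nearest)
        if best is None or cand.rss < best.rss:
            best = cand

    chp, it = _iterate(x, y, chp0, config.tol, config.max_iter)
    n_iter_total += it
    consider(chp, n_iter_total)

    if best is None:
        # bootstrap restarting: a case-resampled refit supplies a fresh
        # starting value for the original data
        for _ in range(config.n_restarts):
            idx = np.sort(rng.integers(0, series.n, series.n))
            xb, yb = x[idx], y[idx]
            start = float(rng.uniform(x[1], x[-2]))
            chp_b, _ = _iterate(xb, yb, start, config.tol, config.max_iter)
            fresh = chp_b if chp_b is not None else start
            chp, it = _iterate(x, y, fresh, config.tol, config.max_iter)
            n_iter_total += it
            consider(chp, n_iter_total)

    if best is None:
        return SegmentedResult(chp=None, b0=np.nan, b11=np.nan, b12=np.nan,
                               rss=np.nan, converged=False,
                               n_iter=n_iter_total, k_nearest=None)
    return best


class SegmentedRegression(BaseEstimator, RegressorMixin):
    """Continuous broken-line regressor with one estimated breakpoint.

    Parameters mirror :class:`SegmentedConfig`; ``random_state`` seeds
    the bootstrap restarts.

    Attributes
    ----------
    chp_ : float or None
        Estimated breakpoint on the x scale (None when no start
        converged — callers must check :attr:`converged_`).
    b0_, b11_, b12_ : float
        Intercept and the two regime slopes of the continuous line.
    rss_ : float
        Residual sum of squares of the converged line.
    converged_ : bool
    n_iter_ : int
    k_nearest_ : int or None
        1-based observation number nearest to ``chp_``.
    """

    def __init__(self, chp0: float | None = None, tol: float = 1e-8,
                 max_iter: int = 30, n_restarts: int = 10,
                 max_retries: int = 3, random_state: int | None = None):
        self.chp0 = chp0
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.max_retries = max_retries
        self.random_state = random_state

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("X must be a single ordered regressor")
            x = x[:, 0]
        series = Series(x, np.asarray(y, dtype=float))
        res = segmented_fit(series, SegmentedConfig(
            chp0=self.chp0, tol=self.tol, max_iter=self.max_iter,
            n_restarts=self.n_restarts, max_retries=self.max_retries,
            seed=self.random_state))
        self.result_ = res
        self.chp_ = res.chp
        self.b0_ = res.b0
        self.b11_ = res.b11
        self.b12_ = res.b12
        self.rss_ = res.rss
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.k_nearest_ = res.k_nearest
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "chp_"):
            raise AttributeError("SegmentedRegression is not fitted yet")
        if self.chp_ is None:
            raise ValueError("fit did not converge; no line to evaluate")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        delta = self.b12_ - self.b11_
        return self.b0_ + self.b11_ * x + delta * np.maximum(x - self.chp_, 0)
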