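"""Residual-permutation changepoint detector (RESPERM).

The detector scans a grid of candidate split points ``K = {s, ..., n-s}``.
At each candidate ``k`` it fits two independent regression lines (before
and after the split) and scores the slope change with an adjusted Cohen's
effect size

    d_k = (b12 - b11) / sigma_beta,

where ``sigma_beta`` pools the standard deviations of the two slope
estimates,

    sigma_beta = sqrt(((k-1) S11^2 + (n-k-1) S12^2) / (n - 2)),

and ``S11, S12`` are estimated by permutation: the pooled length-n
residual vector of the candidate fit is permuted across both regimes,
added back to the fitted values, and both lines are refit for each of
``n_perm`` permutations; the spread of the refit slopes estimates the
slope-coefficient SDs without assuming equal variances in the two
regimes.  The detected changepoint is the smallest ``k`` maximizing
``d_k``.

The estimator targets slope *increases* by default (signed maximization);
``maximize_abs=True`` scores ``|d_k|`` instead for two-sided use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .series import Series, fit_segment_pair

__all__ = ["RespermConfig", "ChangepointResult", "RespermDetector",
           "permutation_slope_sds", "pooled_sigma_beta", "adjusted_cohens_d",
           "detect"]

#: sentinel criterion value for disqualified candidates (zero permutation
#: spread with a nonzero slope difference)
DISQUALIFIED = -math.inf


@dataclass(frozen=True)
class RespermConfig:
    """Tuning parameters of the detector.

    s : grid margin — minimum observations kept in each regime (default
        10, a common rule of thumb for a stable simple regression).
    n_perm : residual permutations per candidate (default 1000).
    seed : seed of the single Generator driving the whole permutation
        stream, consumed in ascending candidate order.
    maximize_abs : score |d_k| instead of signed d_k.
    """

    s: int = 10
    n_perm: int = 1000
    seed: int | None = None
    maximize_abs: bool = False

    def __post_init__(self) -> None:
        if self.s < 2:
            raise ValueError("grid margin s must be >= 2")
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2 for a sample SD")


@dataclass(frozen=True)
class ChangepointResult:
    """Outcome of one detector run.

    k_star is the smallest 1-based observation number attaining the
    maximal criterion; chp_x is the regressor value there, chp_label the
    external label (if the series carries labels).  trace holds the full
    per-candidate (k, d_k) pairs in ascending k.
    """

    k_star: int
    chp_x: float
    chp_label: object | None
    d_star: float
    trace: np.ndarray = field(repr=False)
    seed: int | None = None


def _smallest_argmax(values) -> int:
    """Index of the first maximum — ties resolve to the smallest k."""
    return int(np.argmax(values))


def _permutation_index_matrix(rng: np.random.Generator, n_perm: int,
                              n: int) -> np.ndarray:
    """n_perm independent uniform permutations of 0..n-1, one per row."""
    return rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)


def _slope_contrast(x: np.ndarray) -> np.ndarray:
    """Vector c with slope(x, y) = c @ y for simple OLS."""
    cx = x - x.mean()
    return cx / (cx @ cx)


def permutation_slope_sds(series: Series, k: int, n_perm: int,
                          seed=None, *, perm_index=None
                          ) -> tuple[float, float]:
    """Permutation SDs of the two regime slopes at split ``k``.

    Fits the segment pair at ``k``, pools its n residuals, and for each of
    ``n_perm`` random permutations of the pooled vector rebuilds a
    pseudo-response (fitted + permuted residuals) and refits both regime
    lines.  Returns the sample SDs (ddof=1) of the regime-1 and regime-2
    slope estimates.

    ``seed`` may be an int or an already-advanced Generator (the detector
    passes one Generator through all candidates).  ``perm_index`` lets a
    caller supply an explicit (n_perm, n) permutation-index matrix — used
    to replay the identical stream through an independent oracle.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2: a sample SD of one "
                         "permutation draw is undefined")
    pair = fit_segment_pair(series, k)
    n = series.n
    if perm_index is None:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        perm_index = _permutation_index_matrix(rng, n_perm, n)
    # pseudo-responses, one per row; the fixed design lets each refit
    # slope collapse to a dot product with the centred-x contrast
    y_star = pair.fitted + pair.residuals[perm_index]
    c1 = _slope_contrast(series.x[:k])
    c2 = _slope_contrast(series.x[k:])
    slopes1 = y_star[:, :k] @ c1
    slopes2 = y_star[:, k:] @ c2
    return float(slopes1.std(ddof=1)), float(slopes2.std(ddof=1))


def pooled_sigma_beta(sd_b11: float, sd_b12: float, k: int, n: int) -> float:
    """Pooled SD of the two slope estimates, weighted by regime size."""
    if sd_b11 < 0 or sd_b12 < 0:
        raise ValueError("slope SDs must be nonnegative")
    if not 2 <= k <= n - 2:
        raise ValueError("need 2 <= k <= n - 2")
    return math.sqrt(((k - 1) * sd_b11 ** 2 + (n - k - 1) * sd_b12 ** 2)
                     / (n - 2))


def adjusted_cohens_d(b11: float, b12: float, sigma_beta: float) -> float:
    """Slope-change effect size (b12 - b11) / sigma_beta.

    A zero ``sigma_beta`` arises only for exact-fit (zero-residual)
    regimes; such a candidate is disqualified (-inf) unless the slopes are
    equal, in which case the effect is 0.
    """
    if sigma_beta < 0:
        raise ValueError("sigma_beta must be nonnegative")
    if sigma_beta == 0.0:
        return 0.0 if b12 == b11 else DISQUALIFIED
    return (b12 - b11) / sigma_beta


class RespermDetector(BaseEstimator):
    """Residual-permutation changepoint detector for two-regime lines.

    Scikit-learn style estimator: ``fit(X, y)`` takes the ordered
    regressor as a single-column ``X`` (or 1-d array) and the response
    ``y``; fitted attributes carry the detected changepoint.

    Parameters
    ----------
    s : int, default 10
        Grid margin; candidates range over ``{s, ..., n - s}``.
    n_perm : int, default 1000
        Residual permutations per candidate.
    random_state : int or None
        Seed for the permutation stream; a fixed value makes ``fit``
        bit-reproducible.
    maximize_abs : bool, default False
        Maximize ``|d_k|`` rather than signed ``d_k``.

    Attributes
    ----------
    k_star_ : int
        Smallest 1-based observation number maximizing the criterion.
    chp_x_ : float
        Regressor value at ``k_star_`` (the detected changepoint).
    chp_label_ : object or None
        External label at ``k_star_`` when labels were supplied.
    d_star_ : float
        Criterion value at the optimum.
    trace_ : ndarray of shape (len(K), 2)
        Per-candidate ``(k, d_k)`` pairs in ascending k.

    Examples
    --------
    >>> from resperm.simulate import SimulationSpec, generate_series
    >>> ser = generate_series(SimulationSpec(p=0.01, seed=7))
    >>> det = RespermDetector(n_perm=200, random_state=0)
    >>> det.fit(ser.x, ser.y).k_star_
    50
    """

    def __init__(self, s: int = 10, n_perm: int = 1000,
                 random_state: int | None = None,
                 maximize_abs: bool = False):
        self.s = s
        self.n_perm = n_perm
        self.random_state = random_state
        self.maximize_abs = maximize_abs

    def fit(self, X, y, labels=None):
        """Detect the changepoint of the ordered sample (X, y)."""
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("X must be a single ordered regressor")
            x = x[:, 0]
        series = Series(x, np.asarray(y, dtype=float), labels)
        result = detect(series, RespermConfig(
            s=self.s, n_perm=self.n_perm, seed=self.random_state,
            maximize_abs=self.maximize_abs))
        self.result_ = result
        self.k_star_ = result.k_star
        self.chp_x_ = result.chp_x
        self.chp_label_ = result.chp_label
        self.d_star_ = result.d_star
        self.trace_ = result.trace
        self.n_features_in_ = 1
        self._series = series
        return self

    def predict(self, X):
        """Evaluate the two fitted regime lines, split at ``k_star_``."""
        if not hasattr(self, "k_star_"):
            raise AttributeError("RespermDetector is not fitted yet")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        pair = fit_segment_pair(self._series, self.k_star_)
        out = np.where(x <= self.chp_x_,
                       pair.b01 + pair.b11 * x,
                       pair.b02 + pair.b12 * x)
        return out


def detect(series: Series, config: RespermConfig | None = None
           ) -> ChangepointResult:
    """Run the full grid search; functional counterpart of the estimator.

    One Generator seeded from ``config.seed`` drives the permutation
    stream across all candidates in ascending k, so the entire (k, d_k)
    trace is bit-reproducible for a fixed seed.
    """
    config = config or RespermConfig()
    n = series.n
    if n < 2 * config.s:
        raise ValueError(f"series has n={n} < 2s={2 * config.s} "
                         "observations; shrink the grid margin s")
    rng = np.random.default_rng(config.seed)
    ks = np.arange(config.s, n - config.s + 1)
    ds = np.empty(ks.size)
    # residual scale below which a candidate fit counts as exact
    rss_floor = 1e-20 * max(1.0, float(series.y @ series.y))
    n_exact = 0
    for i, k in enumerate(ks):
        pair = fit_segment_pair(series, int(k))
        sd1, sd2 = permutation_slope_sds(series, int(k), config.n_perm,
                                         seed=rng)
        sigma = pooled_sigma_beta(sd1, sd2, int(k), n)
        n_exact += pair.rss <= rss_floor
        d = adjusted_cohens_d(pair.b11, pair.b12, sigma)
        ds[i] = abs(d) if (config.maximize_abs and math.isfinite(d)) else d
    if n_exact == ks.size or not np.isfinite(ds).any():
        raise ValueError("criterion degenerate on every candidate: the "
                         "series is exactly piecewise linear (all-zero "
                         "residuals), so permutation spread is zero "
                         "everywhere")
    i_star = _smallest_argmax(ds)
    k_star = int(ks[i_star])
    label = series.labels[k_star - 1] if series.labels is not None else None
    return ChangepointResult(
        k_star=k_star, chp_x=float(series.x[k_star - 1]), chp_label=label,
        d_star=float(ds[i_star]),
        trace=np.column_stack([ks.astype(float), ds]),
        seed=config.seed)
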