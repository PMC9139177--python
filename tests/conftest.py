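import numpy as np
import pytest

from resperm.series import Series


@pytest.fixture
def noisy_series():
    """A reproducible 30-point two-regime series with Gaussian noise."""
    rng = np.random.default_rng(20240501)
    x = np.arange(1, 31, dtype=float)
    y = np.where(x <= 15, 1.0, 1.0 + 0.8 * (x - 15)) \
        + 0.5 * rng.standard_normal(30)
    return Series(x, y)


@pytest.fixture
def broken_line_series():
    """Noise-free broken line: flat at 2 up to x=50, unit slope after."""
    x = np.arange(1, 101, dtype=float)
    y = np.where(x <= 50, 2.0, 2.0 + (x - 50))
    return Series(x, y)


def naive_permutation_slope_sds(series, k, perm_index):
    """Double-loop oracle for the permutation slope SDs.

    Explicitly permutes the pooled residual vector, rebuilds the
    pseudo-response and refits each regime line with numpy's polyfit,
    one permutation at a time.  Shares no code with the vectorized path
    beyond the segment-pair fit whose residuals both start from.
    """
    from resperm.series import fit_segment_pair

    pair = fit_segment_pair(series, k)
    slopes1, slopes2 = [], []
    for row in perm_index:
        y_star = pair.fitted + pair.residuals[row]
        b11 = np.polyfit(series.x[:k], y_star[:k], 1)[0]
        b12 = np.polyfit(series.x[k:], y_star[k:], 1)[0]
        slopes1.append(b11)
        slopes2.append(b12)
    return (float(np.std(slopes1, ddof=1)), float(np.std(slopes2, ddof=1)))


def brute_force_breakpoint(x, y, step=0.05):
    """Dense-grid profile-RSS minimizer for the continuous broken line.

    Independent oracle for the segmented estimator: for every candidate
    breakpoint on a fine grid, fit the continuity-constrained line by
    least squares and keep the global RSS minimizer.
    """
    best_rss, best_c = np.inf, None
    for c in np.arange(x[0] + 1.0, x[-1] - 1.0, step):
        above = x > c
        if above.sum() < 2 or (~above).sum() < 2:
            continue
        X = np.column_stack([np.ones_like(x), x, (x - c) * above])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ coef) ** 2).sum())
        if rss < best_rss:
            best_rss, best_c = rss, c
    return best_c, best_rss
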