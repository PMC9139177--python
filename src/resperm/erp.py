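"""Best-of-runs protocol for noisy single-trial amplitude series.

Single-trial ERP amplitude series (e.g. the N250 component across
repeated presentations of a to-be-learned face) are short, noisy and
irregularly spaced: incorrect or artifact trials are discarded, so the
retained observations sit at scattered experiment trial numbers.  Both
detectors here are stochastic, so the protocol runs each one many times
with distinct seeds and keeps the run optimizing the method's own
criterion — maximal effect size for the permutation detector, minimal
residual sum of squares for the segmented fit.

Detection runs on the observation number 1..n (consecutive retained
trials), not the raw trial number; the result is mapped back to the
trial number afterwards.  A synthetic fixture generator emulates the
two-phase learning curve (rising trend, then plateau with smaller
noise) for testing without real EEG data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .detector import ChangepointResult, RespermConfig, detect
from .segmented import SegmentedConfig, SegmentedResult, segmented_fit
from .series import Series

__all__ = ["TrialSeries", "BestOfRunsResult", "best_of_runs",
           "generate_erp_fixture", "read_trials_csv"]


@dataclass(frozen=True)
class TrialSeries:
    """Per-trial amplitudes with their experiment trial numbers.

    trial_number : strictly increasing integer trial indices, possibly
        with gaps from discarded trials.
    amplitude : response values (conventionally µV).
    """

    trial_number: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.trial_number, dtype=int)
        a = np.asarray(self.amplitude, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("trial_number and amplitude must be 1-d and "
                             "equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("trial_number must be strictly increasing")
        object.__setattr__(self, "trial_number", t)
        object.__setattr__(self, "amplitude", a)

    @property
    def n(self) -> int:
        return self.trial_number.size

    def to_series(self) -> Series:
        """Observation-number series (x = 1..n) with trial-number labels."""
        return Series(np.arange(1, self.n + 1, dtype=float),
                      self.amplitude, labels=self.trial_number)


@dataclass(frozen=True)
class BestOfRunsResult:
    """The optimal run among n_runs stochastic repetitions."""

    method: str
    n_runs: int
    best: ChangepointResult | SegmentedResult | None
    criterion: str                      # "max_d" or "min_rss"
    k: int | None
    trial_number: int | None
    all_runs: pd.DataFrame = field(repr=False)

    @property
    def failed(self) -> bool:
        return self.best is None


def best_of_runs(series: TrialSeries, method: str, n_runs: int = 100,
                 base_seed: int = 0,
                 resperm_config: RespermConfig | None = None,
                 segmented_config: SegmentedConfig | None = None
                 ) -> BestOfRunsResult:
    """Run one detector n_runs times and keep its best solution.

    Seeds are ``base_seed .. base_seed + n_runs - 1``.  Ties on the
    criterion keep the earliest run.  All-runs logs carry (seed, k,
    criterion value) per run; failed segmented runs log NaN.
    """
    if method not in ("resperm", "segmented"):
        raise ValueError("method must be 'resperm' or 'segmented'")
    obs = series.to_series()
    rows, results = [], []
    for j in range(n_runs):
        seed = base_seed + j
        if method == "resperm":
            res = detect(obs, replace(resperm_config or RespermConfig(),
                                      seed=seed))
            rows.append({"seed": seed, "k": res.k_star, "value": res.d_star})
        else:
            res = segmented_fit(obs, replace(
                segmented_config or SegmentedConfig(), seed=seed))
            rows.append({"seed": seed,
                         "k": res.k_nearest if not res.failed else None,
                         "value": res.rss if not res.failed else np.nan})
        results.append(res)
    log = pd.DataFrame(rows)

    if method == "resperm":
        j_best = int(np.argmax(log["value"].to_numpy()))
        best = results[j_best]
        k = best.k_star
        criterion = "max_d"
    else:
        vals = log["value"].to_numpy()
        if np.isnan(vals).all():
            return BestOfRunsResult(method=method, n_runs=n_runs, best=None,
                                    criterion="min_rss", k=None,
                                    trial_number=None, all_runs=log)
        j_best = int(np.nanargmin(vals))
        best = results[j_best]
        k = best.k_nearest
        criterion = "min_rss"
    trial = int(series.trial_number[k - 1])
    return BestOfRunsResult(method=method, n_runs=n_runs, best=best,
                            criterion=criterion, k=k, trial_number=trial,
                            all_runs=log)


def generate_erp_fixture(n_obs: int = 60, transition_obs: int = 25,
                         slope1: float = -0.4, plateau_level: float = -10.0,
                         noise_sd1: float = 1.5, noise_sd2: float = 1.0,
                         trial_gap_mean: float = 11.0,
                         seed: int | None = None) -> TrialSeries:
    """Synthetic two-phase learning-curve amplitude series.

    The noise-free amplitude follows a continuous broken line: a linear
    acquisition trend at ``slope1`` per observation reaching
    ``plateau_level`` at ``transition_obs``, flat thereafter
    (consolidation).  The N250 is a negative-going component, so a
    growing component means amplitudes descending to a more negative
    plateau — hence the negative default ``slope1`` and plateau; the
    slope *increases* (toward zero) at the transition, which is the
    regime the signed effect-size detector targets.  Phase-specific
    Gaussian noise (sd1 before, sd2 after) makes the plateau the more
    stable phase.  Trial-number gaps are ``1 + Poisson(trial_gap_mean)``,
    emulating target presentations interspersed among non-target trials
    with discarded epochs.
    """
    if not 0 < transition_obs < n_obs:
        raise ValueError("need 0 < transition_obs < n_obs")
    rng = np.random.default_rng(seed)
    obs = np.arange(1, n_obs + 1)
    trend = np.where(obs <= transition_obs,
                     plateau_level - slope1 * (transition_obs - obs),
                     plateau_level)
    sd = np.where(obs <= transition_obs, noise_sd1, noise_sd2)
    amplitude = trend + sd * rng.standard_normal(n_obs)
    gaps = 1 + rng.poisson(trial_gap_mean, n_obs)
    trial_number = np.cumsum(gaps)
    return TrialSeries(trial_number=trial_number, amplitude=amplitude)


def read_trials_csv(path) -> TrialSeries:
    """Read columns trial_number, amplitude from CSV."""
    df = pd.read_csv(path, comment="#")
    missing = {"trial_number", "amplitude"} - set(df.columns)
    if missing:
        raise ValueError(f"trials CSV must have columns trial_number,"
                         f"amplitude; missing {missing}")
    return TrialSeries(df["trial_number"].to_numpy(int),
                       df["amplitude"].to_numpy(float))
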