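"""Synthetic two-regime series generator for the Monte Carlo study.

The generating model is a continuous broken line on x = 1, 2, ..., n:

    y = 2 + p * e              for x <= chp
    y = 2 + (x - chp) + p*q*e  for x >  chp

so regime 1 is flat at level 2 and regime 2 rises with unit slope; the
two branches meet at the changepoint.  ``p`` scales the noise (3 =
"major", 5 = "dominant"); ``q`` scales regime-2 noise relative to regime
1 (1 = equal variances, 2/3 = smaller after the change, the typical EEG
situation).  Four zero-mean error laws are available, with variances
spanning 1/48 to 1/9:

    normal  : (1/3) * N(0, 1)            var 1/9
    uniform : U(0, 1) - 1/2              var 1/12
    beta22  : Beta(2, 2) - 1/2           var 1/20
    beta26  : Beta(2, 6) - 1/4           var 1/48
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import Series

__all__ = ["SimulationSpec", "ERROR_LAWS", "draw_error", "generate_series"]

ERROR_LAWS = ("normal", "uniform", "beta22", "beta26")


@dataclass(frozen=True)
class SimulationSpec:
    """One Monte Carlo condition for the broken-line generator."""

    n: int = 100
    chp: int = 50
    p: float = 3.0
    q: float = 1.0
    error_law: str = "normal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.chp < self.n:
            raise ValueError("need 0 < chp < n")
        if self.p < 0 or self.q <= 0:
            raise ValueError("need p >= 0 and q > 0")
        if self.error_law not in ERROR_LAWS:
            raise ValueError(f"unknown error law {self.error_law!r}; "
                             f"choose from {ERROR_LAWS}")


def draw_error(error_law: str, size: int, seed=None) -> np.ndarray:
    """i.i.d. zero-mean noise draws from one of the four error laws."""
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if error_law == "normal":
        return rng.standard_normal(size) / 3.0
    if error_law == "uniform":
        return rng.random(size) - 0.5
    if error_law == "beta22":
        return rng.beta(2.0, 2.0, size) - 0.5
    if error_law == "beta26":
        return rng.beta(2.0, 6.0, size) - 0.25
    raise ValueError(f"unknown error law {error_law!r}; "
                     f"choose from {ERROR_LAWS}")


def generate_series(spec: SimulationSpec) -> Series:
    """Generate one series under ``spec``; reproducible given its seed."""
    rng = np.random.default_rng(spec.seed)
    x = np.arange(1, spec.n + 1, dtype=float)
    eps = draw_error(spec.error_law, spec.n, rng)
    below = x <= spec.chp
    y = np.where(below,
                 2.0 + spec.p * eps,
                 2.0 + (x - spec.chp) + spec.p * spec.q * eps)
    return Series(x, y)
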