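"""Shared result containers for the fitted models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["Z90", "PredictionSet", "FixedEffect"]

#: two-sided 90% normal quantile (1.6449)
Z90 = float(norm.ppf(0.95))


@dataclass
class PredictionSet:
    """Point predictions with standard errors and symmetric 90% intervals."""

    mean: np.ndarray
    se: np.ndarray
    lo90: np.ndarray
    hi90: np.ndarray

    @classmethod
    def from_mean_se(cls, mean, se) -> "PredictionSet":
        mean = np.asarray(mean, dtype=float)
        se = np.asarray(se, dtype=float)
        if np.any(se < 0):
            raise ValueError("standard errors must be nonnegative")
        return cls(mean=mean, se=se, lo90=mean - Z90 * se, hi90=mean + Z90 * se)

    def covers(self, truth) -> np.ndarray:
        truth = np.asarray(truth, dtype=float)
        return (self.lo90 <= truth) & (truth <= self.hi90)


@dataclass(frozen=True)
class FixedEffect:
    """One fixed-effect estimate with its 90% confidence interval."""

    name: str
    estimate: float
    se: float
    lo90: float
    hi90: float

    def covers(self, truth: float) -> bool:
        return self.lo90 <= truth <= self.hi90
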