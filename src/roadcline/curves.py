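"""Cline curves and the living-vs-DOR posterior contrast.

The selection signal is the pointwise difference

    Delta(d) = p_melanic,living(d) - p_melanic,DOR(d)

over the surveyed distance range.  Both curves are deterministic functions
of their model's cline parameters, so the posterior of Delta is obtained by
evaluating the difference draw by draw (the two fits are independent, so
draws are paired by index after truncation to a common count) and
summarizing pointwise by the mean and 2.5/97.5 percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import Standardizer
from .mcmc import PosteriorSamples

__all__ = [
    "DEFAULT_DISTANCE_RANGE_KM",
    "ClineCurve",
    "DifferenceCurve",
    "melanism_cline",
    "default_distance_grid",
    "cline_difference_curves",
]

DEFAULT_DISTANCE_RANGE_KM = (0.93, 11.3)


def default_distance_grid(n: int = 100) -> np.ndarray:
    lo, hi = DEFAULT_DISTANCE_RANGE_KM
    return np.linspace(lo, hi, n)


@dataclass(frozen=True)
class ClineCurve:
    """Pointwise posterior summary of proportion melanic along distance."""

    distances_km: np.ndarray
    mean: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray

    def __post_init__(self) -> None:
        for name in ("distances_km", "mean", "lower95", "upper95"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        self._check(0.0, 1.0)

    def _check(self, lo: float, hi: float) -> None:
        n = self.distances_km.size
        if not (self.mean.size == self.lower95.size == self.upper95.size == n):
            raise ValueError("curve arrays must share one grid")
        if np.any(np.diff(self.distances_km) <= 0):
            raise ValueError("distance grid must be strictly increasing")
        eps = 1e-9
        if np.any(self.mean < lo - eps) or np.any(self.mean > hi + eps):
            raise ValueError("curve values outside the admissible range")
        if np.any(self.lower95 > self.mean + eps) or np.any(self.mean > self.upper95 + eps):
            raise ValueError("interval ordering violated (lower95 <= mean <= upper95)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance_km": self.distances_km,
            "mean": self.mean,
            "lower95": self.lower95,
            "upper95": self.upper95,
        })

    def to_dict(self) -> dict:
        """JSON-ready representation (lists keyed like the CSV columns)."""
        return {k: list(map(float, v)) for k, v in (
            ("distance_km", self.distances_km), ("mean", self.mean),
            ("lower95", self.lower95), ("upper95", self.upper95))}


@dataclass(frozen=True)
class DifferenceCurve(ClineCurve):
    """Posterior summary of Delta(d) = p_mel,living(d) - p_mel,DOR(d)."""

    def __post_init__(self) -> None:
        for name in ("distances_km", "mean", "lower95", "upper95"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        self._check(-1.0, 1.0)


def melanism_cline(beta0, beta1, distance_km, standardizer: Standardizer):
    """Proportion melanic over a distance grid: expit(b0 + b1 * z(d)).

    ``beta0``/``beta1`` may be scalars or posterior draw vectors; the
    standardizer must be the one from the model's own fit.
    """
    if standardizer is None:
        raise ValueError("a distance standardizer is required")
    z = standardizer.transform(distance_km)
    b0 = np.atleast_1d(np.asarray(beta0, dtype=float))
    b1 = np.atleast_1d(np.asarray(beta1, dtype=float))
    out = expit(b0[:, None] + b1[:, None] * z[None, :])
    return out[0] if np.isscalar(beta0) or np.ndim(beta0) == 0 else out


def _summarize(draw_matrix: np.ndarray, distances, cls):
    lo, hi = np.quantile(draw_matrix, [0.025, 0.975], axis=0)
    return cls(distances_km=np.asarray(distances, dtype=float),
               mean=draw_matrix.mean(axis=0), lower95=lo, upper95=hi)


def cline_difference_curves(
    post_living: PosteriorSamples,
    post_dor: PosteriorSamples,
    distances_km=None,
) -> tuple[ClineCurve, ClineCurve, DifferenceCurve]:
    """Living and DOR cline curves plus their posterior difference.

    Draws are pooled across chains, truncated to the shorter posterior, and
    paired by index (valid because the two fits are independent).  Warns when
    the grid extends beyond either fit's standardization support.
    """
    if distances_km is None:
        distances_km = default_distance_grid()
    distances_km = np.asarray(distances_km, dtype=float)
    if post_living.n_draws == 0 or post_dor.n_draws == 0:
        raise ValueError("empty posterior")

    std_l = post_living.standardizer("distance")
    std_d = post_dor.standardizer("distance")
    for std in (std_l, std_d):
        z = std.transform(distances_km)
        if np.any(np.abs(z) > 3.5):
            warnings.warn("distance grid extends well beyond the fitted support",
                          stacklevel=2)

    n = min(post_living.pooled().shape[0], post_dor.pooled().shape[0])
    liv = melanism_cline(post_living.pooled("beta0_M")[:n],
                         post_living.pooled("beta1_M")[:n], distances_km, std_l)
    dor = melanism_cline(post_dor.pooled("alpha_D")[:n],
                         post_dor.pooled("beta_D")[:n], distances_km, std_d)
    diff = liv - dor
    return (
        _summarize(liv, distances_km, ClineCurve),
        _summarize(dor, distances_km, ClineCurve),
        _summarize(diff, distances_km, DifferenceCurve),
    )
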