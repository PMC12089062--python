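"""Core data containers for the road-mortality selection analysis.

The study design couples three observation streams along an urban-rural
gradient: repeated point counts and daily camera-trap detection histories of
living squirrels at fixed sites, and opportunistic dead-on-road (DOR) records
from standardized driving surveys.  Everything downstream (likelihoods, MCMC,
cline contrasts) consumes the typed containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Standardizer",
    "LatentAbundance",
    "SiteDataset",
    "DORRecord",
    "RiskDataset",
]


@dataclass(frozen=True)
class Standardizer:
    """Mean/SD pair used to center and scale a covariate before fitting.

    The SD uses the n-1 denominator.  Instances are stored with every fit so
    cline curves can be evaluated on the natural (km) scale afterwards.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean) or not np.isfinite(self.sd):
            raise ValueError("standardizer constants must be finite")
        if self.sd <= 0:
            raise ValueError("standardizer SD must be positive")

    def transform(self, values):
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, values):
        return np.asarray(values, dtype=float) * self.sd + self.mean

    @classmethod
    def fit(cls, values) -> "Standardizer":
        values = np.asarray(values, dtype=float)
        if values.size < 2 or np.ptp(values) == 0:
            raise ValueError("need at least two distinct values to standardize")
        return cls(mean=float(values.mean()), sd=float(values.std(ddof=1)))


class LatentAbundance(NamedTuple):
    """True (unobserved) squirrel numbers at one site: total and melanic."""

    site: int
    n_total: int
    n_melanic: int

    def validate(self) -> None:
        if not (0 <= self.n_melanic <= self.n_total):
            raise ValueError(
                f"site {self.site}: need 0 <= n_melanic <= n_total, "
                f"got {self.n_melanic} / {self.n_total}"
            )


class DORRecord(NamedTuple):
    """One road-killed squirrel: coat-color morph and distance to city center."""

    distance_km: float
    morph: int  # 1 = melanic, 0 = gray


MORPHS = ("melanic", "gray")


@dataclass
class SiteDataset:
    """Living-squirrel evidence for one survey season.

    Attributes
    ----------
    sites : DataFrame with columns ``site``, ``distance_km``, ``camera_flag``.
    counts : DataFrame with columns ``site``, ``survey``, ``temperature_std``,
        ``count_melanic``, ``count_gray`` (3-min point counts).
    cameras : DataFrame with columns ``site``, ``day``, ``temperature_std``,
        ``det_melanic``, ``det_gray`` (daily detection indicators).
    distance_std, temperature_std : the standardizers applied before fitting.
    """

    sites: pd.DataFrame
    counts: pd.DataFrame
    cameras: pd.DataFrame
    distance_std: Standardizer
    temperature_std: Standardizer

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def distance_z(self) -> np.ndarray:
        return self.distance_std.transform(self.sites["distance_km"].to_numpy())

    def validate(self) -> None:
        required = {
            "sites": ["site", "distance_km", "camera_flag"],
            "counts": ["site", "survey", "temperature_std", "count_melanic", "count_gray"],
            "cameras": ["site", "day", "temperature_std", "det_melanic", "det_gray"],
        }
        for name, cols in required.items():
            frame = getattr(self, name)
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise ValueError(f"{name} table is missing columns {missing}")
        if (self.sites["distance_km"] <= 0).any():
            raise ValueError("distances to city center must be positive")
        if self.sites["site"].duplicated().any():
            raise ValueError("duplicate site ids")
        for col in ("count_melanic", "count_gray"):
            if (self.counts[col] < 0).any():
                raise ValueError(f"negative values in counts column {col!r}")
        for col in ("det_melanic", "det_gray"):
            if not self.cameras[col].isin([0, 1]).all():
                raise ValueError(f"camera column {col!r} must be binary")
        known = set(self.sites["site"])
        for name in ("counts", "cameras"):
            unknown = set(getattr(self, name)["site"]) - known
            if unknown:
                raise ValueError(f"{name} table references unknown sites {sorted(unknown)}")
        no_cam = set(self.sites.loc[self.sites["camera_flag"] == 0, "site"])
        if set(self.cameras["site"]) & no_cam:
            raise ValueError("camera records present for sites without cameras")
        surveyed = set(self.counts["site"])
        if known - surveyed:
            raise ValueError("every site needs at least one point-count survey")


@dataclass
class RiskDataset:
    """Location-level road/landscape covariates with a DOR-vs-reference outcome.

    ``frame`` holds one row per location; ``balanced`` records whether cases
    and references were sampled to equal size (the matched design) or drawn
    from the generating model's marginal prevalence.
    """

    frame: pd.DataFrame
    morph: str = "gray"
    balanced: bool = True

    COLUMNS = (
        "outcome",
        "speed",
        "traffic",
        "crossings",
        "habitat_split",
        "pop_density",
        "forest_cover",
        "fragmentation",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"risk table is missing columns {missing}")
        f = self.frame
        if not f["outcome"].isin([0, 1]).all():
            raise ValueError("outcome must be binary (1=DOR, 0=reference)")
        if not f["crossings"].isin([0, 1]).all():
            raise ValueError("crossings must be binary")
        for col in ("traffic", "pop_density", "fragmentation"):
            if (f[col] <= 0).any():
                raise ValueError(f"{col} must be positive (it is log-transformed downstream)")
        for col in ("habitat_split", "forest_cover"):
            if ((f[col] < 0) | (f[col] > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")
        if not np.isfinite(f[list(self.COLUMNS)].to_numpy(dtype=float)).all():
            raise ValueError("non-finite covariate values")

    @property
    def group_sizes(self) -> tuple[int, int]:
        n1 = int((self.frame["outcome"] == 1).sum())
        return n1, len(self.frame) - n1
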