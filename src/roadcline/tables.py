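"""Contingency statistics for the citizen-science morph x mortality tables.

The range-wide comparison reduces to a 2x2 table of coat-color morph
(melanic, gray) against status (dead on road, alive).  Association is tested
with Pearson's chi-square with Yates' continuity correction (the clamped R
convention, so an exactly independent table yields 0), effect size with
Cramer's V from the uncorrected statistic, and per-morph DOR proportions are
intervalled with the Agresti-Coull adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

__all__ = [
    "ContingencyTable2x2",
    "expected_counts",
    "chi2_uncorrected",
    "yates_chi2",
    "yates_chi2_test",
    "cramers_v",
    "agresti_coull_interval",
    "filter_classifications",
]

MORPH_LABELS = ("melanic", "gray")
STATUS_LABELS = ("dead", "alive")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Integer cells ``O[morph][status]`` with morph rows and status columns."""

    cells: np.ndarray  # shape (2, 2): rows (melanic, gray), cols (dead, alive)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.int64)
        if cells.shape != (2, 2):
            raise ValueError("expected a 2x2 table")
        if (cells < 0).any():
            raise ValueError("cell counts must be nonnegative")
        object.__setattr__(self, "cells", cells)

    @classmethod
    def from_totals(
        cls, total_melanic: int, dead_melanic: int, total_gray: int, dead_gray: int
    ) -> "ContingencyTable2x2":
        for total, dead, morph in (
            (total_melanic, dead_melanic, "melanic"),
            (total_gray, dead_gray, "gray"),
        ):
            if dead < 0 or total < 0:
                raise ValueError("counts must be nonnegative")
            if dead > total:
                raise ValueError(f"dead {morph} count exceeds its total")
        return cls(np.array([
            [dead_melanic, total_melanic - dead_melanic],
            [dead_gray, total_gray - dead_gray],
        ]))

    @property
    def n(self) -> int:
        return int(self.cells.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(MORPH_LABELS), columns=list(STATUS_LABELS))

    def require_positive_margins(self) -> None:
        if (self.cells.sum(axis=1) == 0).any() or (self.cells.sum(axis=0) == 0).any():
            raise ValueError("every row and column margin must be positive")


def expected_counts(table: ContingencyTable2x2) -> np.ndarray:
    """Expected cells under independence: row_i * col_j / N (margins preserved)."""
    table.require_positive_margins()
    o = table.cells.astype(float)
    return np.outer(o.sum(axis=1), o.sum(axis=0)) / o.sum()


def chi2_uncorrected(table: ContingencyTable2x2) -> float:
    e = expected_counts(table)
    o = table.cells.astype(float)
    return float(((o - e) ** 2 / e).sum())


def yates_chi2(table: ContingencyTable2x2) -> float:
    """Yates-corrected statistic with the correction clamped at min|O-E|.

    The clamp (``c = min(0.5, min|O-E|)``) keeps an exactly independent table
    at 0 instead of a spurious positive value.
    """
    e = expected_counts(table)
    o = table.cells.astype(float)
    diff = np.abs(o - e)
    c = min(0.5, float(diff.min()))
    return float(((diff - c) ** 2 / e).sum())


def yates_chi2_test(table: ContingencyTable2x2) -> tuple[float, float]:
    """Statistic and p-value (1 df) of the corrected test."""
    stat = yates_chi2(table)
    return stat, float(chi2_dist.sf(stat, df=1))


def cramers_v(table: ContingencyTable2x2) -> float:
    """Effect size sqrt(chi2 / (N * min(r-1, c-1))) from the uncorrected statistic."""
    return float(np.sqrt(chi2_uncorrected(table) / table.n))  # min(r-1, c-1) = 1 for 2x2


def agresti_coull_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Adjusted-count binomial interval, truncated to [0, 1]."""
    if not 0 <= successes <= n or n <= 0:
        raise ValueError("need 0 <= successes <= n with n positive")
    if not 0 < level < 1:
        raise ValueError("level must lie strictly between 0 and 1")
    z = norm.ppf(1 - (1 - level) / 2)
    n_tilde = n + z**2
    p_tilde = (successes + z**2 / 2) / n_tilde
    half = z * np.sqrt(p_tilde * (1 - p_tilde) / n_tilde)
    return float(max(0.0, p_tilde - half)), float(min(1.0, p_tilde + half))


def filter_classifications(
    votes: pd.DataFrame,
    min_classifiers: int = 10,
    min_agreement: float = 0.8,
) -> pd.DataFrame:
    """Consensus filter for crowdsourced image classifications.

    ``votes`` has one row per (image, field, choice) vote.  An image is
    retained when every field has at least ``min_classifiers`` votes and its
    modal choice reaches ``min_agreement``; the returned frame holds one row
    per retained image with the consensus choice per field.
    """
    required = {"image_id", "field", "choice"}
    if missing := required - set(votes.columns):
        raise ValueError(f"votes table is missing columns {sorted(missing)}")
    out = []
    for image_id, img in votes.groupby("image_id"):
        consensus: dict = {"image_id": image_id}
        ok = True
        for fname, fvotes in img.groupby("field"):
            tally = fvotes["choice"].value_counts()
            if tally.sum() < min_classifiers or tally.iloc[0] / tally.sum() < min_agreement:
                ok = False
                break
            consensus[fname] = tally.index[0]
        if ok:
            out.append(consensus)
    return pd.DataFrame(out)
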