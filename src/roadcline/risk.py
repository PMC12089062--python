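"""Morph-specific road-mortality risk effects with causal adjustment.

For each road/landscape exposure of interest the direct effect on mortality
risk is estimated by a Firth logistic regression of the DOR-vs-reference
outcome on the exposure plus a backdoor adjustment set read off the causal
DAG.  Human population density, forest fragmentation and traffic volume
enter on the log scale (log-odds linearity); crossings is a binary
indicator and habitat split a proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dag import OUTCOME, CausalDAG, backdoor_sets, default_risk_dag
from .data import RiskDataset
from .firth import FirthFit, firth_logistic

__all__ = ["RiskEffect", "estimate_risk_effect", "LOG_TRANSFORMED"]

LOG_TRANSFORMED = ("pop_density", "fragmentation", "traffic")


@dataclass(frozen=True)
class RiskEffect:
    """Adjusted effect of one exposure on road-mortality risk."""

    exposure: str
    morph: str
    estimate: float
    se: float
    p_value: float
    adjustment_set: tuple[str, ...]
    minimal_sets: tuple[tuple[str, ...], ...]
    fit: FirthFit

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "morph": self.morph,
            "estimate": self.estimate,
            "se": self.se,
            "p_value": self.p_value,
            "adjustment_set": list(self.adjustment_set),
            "minimal_sets": [list(s) for s in self.minimal_sets],
            "converged": self.fit.converged,
        }


def _analysis_column(frame: pd.DataFrame, name: str) -> np.ndarray:
    col = frame[name].to_numpy(dtype=float)
    if name in LOG_TRANSFORMED:
        if (col <= 0).any():
            raise ValueError(f"{name} must be positive for the log transform")
        return np.log(col)
    return col


def estimate_risk_effect(
    dataset: RiskDataset,
    exposure: str,
    dag: CausalDAG | None = None,
    adjustment: tuple[str, ...] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> RiskEffect:
    """Adjusted Firth-logistic effect of ``exposure`` on mortality risk.

    The adjustment set defaults to the first (smallest, lexicographic)
    minimal backdoor set whose members are all observed covariates; pass
    ``adjustment`` to override.  Raises when the exposure is absent or no
    fully observed adjustment set exists.
    """
    frame = dataset.frame
    if exposure not in frame.columns:
        raise KeyError(f"exposure {exposure!r} not present in the risk dataset")
    dag = dag or default_risk_dag()
    observed = set(frame.columns) - {"outcome"}

    sets = backdoor_sets(dag, exposure, OUTCOME)
    if adjustment is not None:
        chosen = tuple(adjustment)
        if not set(chosen) <= observed:
            raise ValueError("override adjustment set contains unobserved covariates")
    else:
        usable = [s for s in sets if set(s) <= observed]
        if not usable:
            raise ValueError(
                f"no minimal backdoor set for {exposure!r} is fully observed; "
                f"candidates were {[sorted(s) for s in sets]}"
            )
        chosen = tuple(sorted(usable[0]))

    cols = [exposure, *chosen]
    design = np.column_stack(
        [np.ones(len(frame))] + [_analysis_column(frame, c) for c in cols]
    )
    fit = firth_logistic(design, frame["outcome"].to_numpy(), tol=tol, max_iter=max_iter)
    return RiskEffect(
        exposure=exposure,
        morph=dataset.morph,
        estimate=float(fit.coef[1]),
        se=float(fit.se[1]),
        p_value=float(fit.p_values[1]),
        adjustment_set=chosen,
        minimal_sets=tuple(tuple(sorted(s)) for s in sets),
        fit=fit,
    )
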