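"""End-to-end orchestration: simulate -> fit -> contrast -> risk -> tables.

A single :class:`PipelineConfig` (YAML- or dict-backed) drives the whole
workflow; one global seed deterministically expands into per-stage seeds via
``numpy.random.SeedSequence``, so re-running a config reproduces every
numeric output byte for byte.  Logging goes to stderr; numeric results only
ever land in files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import cline_difference_curves
from .dag import EXPOSURES, default_risk_dag
from .fit import fit_dor_model, fit_living_model
from .io import (
    write_citizen_table,
    write_dor_records,
    write_risk_dataset,
    write_site_dataset,
)
from .mcmc import MCMCConfig, gelman_rubin, posterior_summary
from .risk import estimate_risk_effect
from .synthetic import (
    RiskTruth,
    SurveyDesign,
    TruthParams,
    make_citizen_table,
    simulate_dor_records,
    simulate_observations,
    simulate_risk_dataset,
    simulate_squirrel_landscape,
)
from .tables import agresti_coull_interval, cramers_v, expected_counts, yates_chi2_test

__all__ = ["PipelineConfig", "run_full_pipeline", "stage_seeds"]

log = logging.getLogger("roadcline")

# SquirrelMapper classification totals (melanic total/dead, gray total/dead)
DEFAULT_CITIZEN_TOTALS = (12_705, 174, 96_025, 1_581)


@dataclass
class PipelineConfig:
    outdir: str = "results/run"
    seed: int = 0
    n_sites: int = 41
    n_dor: int = 141
    n_risk_per_group: int = 141
    truth: TruthParams = field(default_factory=TruthParams)
    design: SurveyDesign = field(default_factory=SurveyDesign)
    mcmc_living: MCMCConfig = field(default_factory=lambda: MCMCConfig(
        n_chains=3, n_adapt=900, n_iter=2100, n_burnin=600, thin=3))
    mcmc_dor: MCMCConfig = field(default_factory=lambda: MCMCConfig(
        n_chains=3, n_adapt=1500, n_iter=6000, n_burnin=1000, thin=5))
    grid_points: int = 100
    citizen_totals: tuple[int, int, int, int] = DEFAULT_CITIZEN_TOTALS
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "truth" in kwargs:
            t = dict(kwargs["truth"])
            for key in ("det_melanic", "det_gray", "distance_range_km"):
                if key in t:
                    t[key] = tuple(t[key])
            kwargs["truth"] = TruthParams(**t)
        if "design" in kwargs:
            kwargs["design"] = SurveyDesign(**kwargs["design"])
        for key in ("mcmc_living", "mcmc_dor"):
            if key in kwargs:
                kwargs[key] = MCMCConfig(**kwargs[key])
        if "citizen_totals" in kwargs:
            kwargs["citizen_totals"] = tuple(kwargs["citizen_totals"])
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seed expansion from the global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic data; returns paths and key summaries."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    s_land, s_obs, s_dor, s_living_fit, s_dor_fit, s_risk_g, s_risk_m, _ = seeds

    def _stage(name):
        log.info("stage: %s", name)

    try:
        _stage("simulate")
        sites, latents, dist_std = simulate_squirrel_landscape(
            config.truth, config.n_sites, s_land,
            n_camera_sites=config.design.n_camera_sites)
        data = simulate_observations(
            config.truth, sites, latents, config.design, s_obs, distance_std=dist_std)
        dor = simulate_dor_records(config.truth, config.n_dor, s_dor)
        data_paths = write_site_dataset(data, outdir / "data", truth=config.truth,
                                        seed=config.seed)
        write_dor_records(dor, outdir / "data" / "dor.csv")
    except Exception as err:
        raise RuntimeError(f"stage 'simulate' failed: {err}") from err

    try:
        _stage("fit-cline")
        post_living = fit_living_model(
            data, dataclasses.replace(config.mcmc_living, seed=s_living_fit))
        _stage("fit-dor")
        post_dor = fit_dor_model(
            dor, dataclasses.replace(config.mcmc_dor, seed=s_dor_fit))
    except Exception as err:
        raise RuntimeError(f"stage 'fit' failed: {err}") from err

    post_living.to_frame().to_csv(outdir / "posterior_living.csv", index=False)
    post_dor.to_frame().to_csv(outdir / "posterior_dor.csv", index=False)

    rhat = {**gelman_rubin(post_living), **gelman_rubin(post_dor)}
    converged = all(v < 1.1 for v in rhat.values())
    (outdir / "rhat_report.json").write_text(json.dumps(
        {"rhat": rhat, "threshold": 1.1, "converged": converged,
         "acceptance_living": post_living.meta["acceptance_rates"],
         "acceptance_dor": post_dor.meta["acceptance_rates"]}, indent=2))
    if not converged:
        log.warning("convergence flagged: some R-hat >= 1.1 (see rhat_report.json)")

    summary = pd.concat([posterior_summary(post_living), posterior_summary(post_dor)])
    summary["excludes_zero"] = (summary["lower95"] > 0) | (summary["upper95"] < 0)
    summary["rhat"] = [rhat[name] for name in summary.index]
    summary.rename_axis("parameter").to_csv(outdir / "summary_table.csv")

    try:
        _stage("contrast")
        grid = np.linspace(*config.truth.distance_range_km, config.grid_points)
        liv_curve, dor_curve, diff_curve = cline_difference_curves(
            post_living, post_dor, grid)
    except Exception as err:
        raise RuntimeError(f"stage 'contrast' failed: {err}") from err
    liv_curve.to_frame().to_csv(outdir / "cline_living.csv", index=False)
    dor_curve.to_frame().to_csv(outdir / "cline_dor.csv", index=False)
    diff_curve.to_frame().to_csv(outdir / "difference_curve.csv", index=False)

    try:
        _stage("fit-risk")
        dag = default_risk_dag()
        risk_out = {}
        for morph, truth_cls, seed in (
            ("gray", RiskTruth.default_gray(), s_risk_g),
            ("melanic", RiskTruth.default_melanic(), s_risk_m),
        ):
            dataset = simulate_risk_dataset(truth_cls, config.n_risk_per_group,
                                            seed, morph=morph)
            write_risk_dataset(dataset, outdir / "data" / f"risk_{morph}.csv")
            risk_out[morph] = [
                estimate_risk_effect(dataset, exposure, dag).to_dict()
                for exposure in EXPOSURES
            ]
        (outdir / "risk_effects.json").write_text(json.dumps(risk_out, indent=2))
    except Exception as err:
        raise RuntimeError(f"stage 'fit-risk' failed: {err}") from err

    try:
        _stage("table-stats")
        table = make_citizen_table(*config.citizen_totals)
        write_citizen_table(table, outdir / "data" / "citizen.csv")
        stat, p = yates_chi2_test(table)
        tm, dm, tg, dg = config.citizen_totals
        citizen = {
            "chi2_yates": stat,
            "p_value": p,
            "cramers_v": cramers_v(table),
            "expected": expected_counts(table).tolist(),
            "dor_proportion_ci": {
                "melanic": agresti_coull_interval(dm, tm),
                "gray": agresti_coull_interval(dg, tg),
            },
            "n": table.n,
        }
        (outdir / "citizen_stats.json").write_text(json.dumps(citizen, indent=2))
    except Exception as err:
        raise RuntimeError(f"stage 'table-stats' failed: {err}") from err

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": config.to_jsonable(),
        "outputs": sorted(str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "outdir": str(outdir),
        "converged": converged,
        "rhat": rhat,
        "summary": summary,
        "difference_curve": diff_curve,
        "risk": risk_out,
        "citizen": citizen,
        "data_paths": data_paths,
    }
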