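"""CSV/JSON readers and writers for every pipeline artifact.

Schemas (all plain CSV):
  sites.csv         site,distance_km,camera_flag
  point_counts.csv  site,survey,temperature_std,count_melanic,count_gray
  cameras.csv       site,day,temperature_std,det_melanic,det_gray
  dor.csv           distance_km,morph
  risk_<morph>.csv  outcome,speed,traffic,crossings,habitat_split,
                    pop_density,forest_cover,fragmentation
  citizen.csv       2x2 table, rows melanic/gray, columns dead/alive
  dag.csv           parent,child

A JSON sidecar (``dataset.json``) stores the standardizer constants, the
generating truth, and the seed so a synthetic dataset round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import RiskDataset, SiteDataset, Standardizer
from .synthetic import TruthParams
from .tables import MORPH_LABELS, STATUS_LABELS, ContingencyTable2x2

__all__ = [
    "write_site_dataset",
    "read_site_dataset",
    "write_dor_records",
    "read_dor_records",
    "write_risk_dataset",
    "read_risk_dataset",
    "write_citizen_table",
    "read_citizen_table",
    "read_survey_tables",
]


def _require_columns(frame: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")
    block = frame[list(cols)]
    non_numeric = [c for c in cols if not np.issubdtype(block[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{what} has non-numeric cells in columns {non_numeric}")


def write_site_dataset(data: SiteDataset, outdir, truth: TruthParams | None = None,
                       seed: int | None = None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": outdir / "sites.csv",
        "counts": outdir / "point_counts.csv",
        "cameras": outdir / "cameras.csv",
        "sidecar": outdir / "dataset.json",
    }
    data.sites.to_csv(paths["sites"], index=False)
    data.counts.to_csv(paths["counts"], index=False)
    data.cameras.to_csv(paths["cameras"], index=False)
    sidecar = {
        "distance_mean": data.distance_std.mean,
        "distance_sd": data.distance_std.sd,
        "temperature_mean": data.temperature_std.mean,
        "temperature_sd": data.temperature_std.sd,
        "seed": seed,
        "truth": dataclasses.asdict(truth) if truth is not None else None,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return {k: str(v) for k, v in paths.items()}


def read_site_dataset(indir) -> SiteDataset:
    indir = Path(indir)
    sites = pd.read_csv(indir / "sites.csv")
    counts = pd.read_csv(indir / "point_counts.csv")
    cameras = pd.read_csv(indir / "cameras.csv")
    _require_columns(sites, ["site", "distance_km", "camera_flag"], "sites.csv")
    _require_columns(
        counts,
        ["site", "survey", "temperature_std", "count_melanic", "count_gray"],
        "point_counts.csv",
    )
    _require_columns(
        cameras,
        ["site", "day", "temperature_std", "det_melanic", "det_gray"],
        "cameras.csv",
    )
    sidecar = json.loads((indir / "dataset.json").read_text())
    return SiteDataset(
        sites=sites,
        counts=counts,
        cameras=cameras,
        distance_std=Standardizer(sidecar["distance_mean"], sidecar["distance_sd"]),
        temperature_std=Standardizer(sidecar["temperature_mean"], sidecar["temperature_sd"]),
    )


def write_dor_records(records: pd.DataFrame, path) -> None:
    records[["distance_km", "morph"]].to_csv(path, index=False)


def read_dor_records(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, ["distance_km", "morph"], "DOR table")
    if not frame["morph"].isin([0, 1]).all():
        raise ValueError("morph must be binary (1=melanic, 0=gray)")
    if (frame["distance_km"] <= 0).any():
        raise ValueError("distances must be positive")
    return frame


def write_risk_dataset(dataset: RiskDataset, path) -> None:
    dataset.frame[list(RiskDataset.COLUMNS)].to_csv(path, index=False)


def read_risk_dataset(path, morph: str = "gray", balanced: bool = True) -> RiskDataset:
    frame = pd.read_csv(path)
    _require_columns(frame, RiskDataset.COLUMNS, "risk table")
    return RiskDataset(frame=frame, morph=morph, balanced=balanced)


def write_citizen_table(table: ContingencyTable2x2, path) -> None:
    table.to_frame().rename_axis("morph").to_csv(path)


def read_citizen_table(path) -> ContingencyTable2x2:
    frame = pd.read_csv(path, index_col=0)
    missing = [c for c in STATUS_LABELS if c not in frame.columns]
    if missing:
        raise ValueError(f"citizen table is missing columns {missing}")
    rows = [r for r in MORPH_LABELS if r not in frame.index]
    if rows:
        raise ValueError(f"citizen table is missing rows {rows}")
    return ContingencyTable2x2(
        frame.loc[list(MORPH_LABELS), list(STATUS_LABELS)].to_numpy())


def read_survey_tables(paths: dict):
    """Load every input stage at once.

    ``paths`` maps stage names (``sites`` pointing at the site-dataset
    directory, ``dor``, ``risk``, ``citizen``) to locations; absent stages
    yield None.  Returns (SiteDataset, DOR frame, RiskDataset, table).
    """
    data = read_site_dataset(paths["sites"]) if "sites" in paths else None
    dor = read_dor_records(paths["dor"]) if "dor" in paths else None
    risk = read_risk_dataset(paths["risk"]) if "risk" in paths else None
    citizen = read_citizen_table(paths["citizen"]) if "citizen" in paths else None
    return data, dor, risk, citizen
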