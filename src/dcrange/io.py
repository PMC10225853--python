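"""Serialization of grids, stacks, surveys and records.

Grids travel as TIFF (one file per predictor with one band per year, written
with :mod:`tifffile`; georeferencing is out of scope, a sentinel tag marks
the grid as abstract cells) alongside an ``.npz`` fallback; tables as CSV;
standardization/trend records and configs as JSON/YAML sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .climate import ClimateStack, StdRecord, TrendRecord

SURVEY_COLUMNS = ["site_id", "x_cell", "y_cell", "year", "count"]


def write_grid_tiff(path, grid: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(grid, dtype=np.float32),
                     metadata={"crs": "cell-grid (no CRS)"})


def read_grid_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)))


def write_climate_stack(path_prefix, stack: ClimateStack) -> None:
    """One multi-band TIFF per predictor plus a JSON sidecar with years/records."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for pred, arr in stack.data.items():
        write_grid_tiff(f"{prefix}_{pred}.tif", arr)
    meta = {
        "years": stack.years.tolist(),
        "cell_km": stack.cell_km,
        "predictors": list(stack.data),
        "std": None if stack.std is None else {
            p: {"mean": r.mean, "sd": r.sd, "reference_years": list(r.reference_years)}
            for p, r in stack.std.items()
        },
    }
    Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=1))


def read_climate_stack(path_prefix) -> ClimateStack:
    prefix = Path(path_prefix)
    meta = json.loads(Path(f"{prefix}_meta.json").read_text())
    data = {p: read_grid_tiff(f"{prefix}_{p}.tif").astype(float) for p in meta["predictors"]}
    std = None
    if meta["std"] is not None:
        std = {
            p: StdRecord(mean=r["mean"], sd=r["sd"], reference_years=tuple(r["reference_years"]))
            for p, r in meta["std"].items()
        }
    return ClimateStack(years=np.asarray(meta["years"]), data=data, std=std,
                        cell_km=meta["cell_km"])


def write_survey(path, survey: pd.DataFrame) -> None:
    survey[SURVEY_COLUMNS].to_csv(path, index=False)


def read_survey(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trend(path, trend: TrendRecord) -> None:
    Path(path).write_text(json.dumps({
        "slope": trend.slope, "intercept": trend.intercept,
        "first_year": trend.first_year, "last_year": trend.last_year,
    }, indent=1))


def read_trend(path) -> TrendRecord:
    d = json.loads(Path(path).read_text())
    return TrendRecord(slope=d["slope"], intercept=d["intercept"],
                       first_year=d["first_year"], last_year=d["last_year"])


def write_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
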