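"""Apply a trained model across a gridded soil-property table.

Turns a table of grid cells (lat, lon, six soil properties; one row per
location) into per-compound log Kd predictions: cells with gaps are either
completed with a fitted soil imputer or marked ``nodata``; the compound is
speciated at each cell's pH; predictions outside the training applicability
ranges carry an ``out_of_domain`` flag but are still emitted.  Input and
output are plain CSV tables -- rasterization is left to GIS tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .harmonize import DataError
from .impute import SOIL_FEATURES, SoilImputer
from .model import StackedModel
from .registry import CompoundRegistry
from .speciation import speciate

__all__ = ["GRID_COLUMNS", "predict_map"]

GRID_COLUMNS = ["lat", "lon"] + SOIL_FEATURES


def predict_map(
    model: StackedModel,
    grid: pd.DataFrame,
    compound_id: str,
    registry: CompoundRegistry,
    imputer: SoilImputer | None = None,
) -> pd.DataFrame:
    """Predict log Kd of one compound for every grid cell.

    Output has one row per input cell with added columns ``compound_id``,
    ``log_kd``, ``kd``, ``nodata`` and ``out_of_domain``; ``nodata`` cells
    (soil gaps and no imputer, or nothing to impute from) carry no prediction.
    """
    if len(grid) == 0:
        raise DataError("empty grid")
    missing_cols = [c for c in GRID_COLUMNS if c not in grid.columns]
    if missing_cols:
        raise DataError(f"grid table lacks columns: {missing_cols}")
    compound = registry.get(compound_id)

    out = grid.reset_index(drop=True).copy()
    if ((out["lat"].abs() > 90) | (out["lon"].abs() > 180)).any():
        raise DataError("coordinates outside WGS84 bounds")

    soil = out[SOIL_FEATURES].astype(float)
    nodata = soil.isna().all(axis=1)
    if imputer is not None:
        fillable = ~nodata
        if fillable.any():
            soil.loc[fillable] = imputer.transform(soil.loc[fillable])
    nodata = soil.isna().any(axis=1)

    out["compound_id"] = compound.id
    out["nodata"] = nodata
    out["log_kd"] = np.nan
    out["kd"] = np.nan
    out["out_of_domain"] = False

    valid = ~nodata
    if valid.any():
        cells = soil.loc[valid].copy()
        states = [speciate(compound, ph) for ph in cells["ph"]]
        cells["mw_effective"] = [s.mw_effective for s in states]
        cells["charge_density"] = [s.charge_density for s in states]
        cells["log_kow"] = compound.log_kow
        log_kd = model.predict(cells)
        out.loc[valid, "log_kd"] = log_kd
        out.loc[valid, "kd"] = 10.0 ** log_kd
        out.loc[valid, "out_of_domain"] = model.out_of_domain(cells)
    return out
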