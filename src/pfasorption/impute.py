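"""K-nearest-neighbor imputation of missing soil properties.

Literature sorption records frequently omit one or more of the six soil
properties the model needs (pH, CEC, Corg, sand, silt, clay).  A complete
reference table of soils -- in practice a worldwide sample of topsoil
properties -- is used to fill the gaps: each incomplete soil is matched to
its k nearest reference soils using a missing-value-aware Euclidean distance
over min-max-scaled properties, and each missing value is the uniform mean
of the neighbors' values.

The distance over the observed coordinates is rescaled by the fraction of
coordinates observed (scikit-learn's ``nan_euclidean`` convention), so soils
with different missingness patterns remain comparable.  Imputation is fully
deterministic.  Coordinates (lat/lon), when present in a reference table,
are metadata only and never used as distance features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .harmonize import DataError, SoilSample

__all__ = ["SOIL_FEATURES", "SoilImputer", "load_reference_table"]

SOIL_FEATURES = ["ph", "cec", "corg", "sand", "silt", "clay"]


def load_reference_table(path: str | Path) -> pd.DataFrame:
    """Read a reference soil CSV (columns ``SOIL_FEATURES``; lat/lon optional)."""
    df = pd.read_csv(path)
    missing = [c for c in SOIL_FEATURES if c not in df.columns]
    if missing:
        raise DataError(f"reference table lacks columns: {missing}")
    return df


@dataclass
class SoilImputer:
    """KNN imputer over the six soil model properties.

    Fit on a complete reference table; ``transform`` fills missing values in
    query soils from the k nearest reference rows (uniform weights).  Scaling
    bounds come from the reference table only.
    """

    k: int = 5

    def fit(self, reference: pd.DataFrame, k: int | None = None) -> "SoilImputer":
        if k is not None:
            self.k = k
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        ref = reference[SOIL_FEATURES].astype(float)
        if ref.isna().any().any():
            raise DataError("reference table must be complete")
        if len(ref) < self.k:
            raise ValueError(f"k={self.k} exceeds reference size {len(ref)}")
        self.lo_ = ref.min().to_numpy()
        self.hi_ = ref.max().to_numpy()
        span = self.hi_ - self.lo_
        if np.any(span <= 0):
            bad = [f for f, s in zip(SOIL_FEATURES, span) if s <= 0]
            raise DataError(f"constant reference column(s): {bad}")
        self.reference_ = ref.to_numpy()
        self._scaled_ref = (self.reference_ - self.lo_) / span
        self._knn = KNNImputer(n_neighbors=self.k, weights="uniform")
        self._knn.fit(self._scaled_ref)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "reference_"):
            raise RuntimeError("imputer is not fitted")

    def transform(self, soils: pd.DataFrame) -> pd.DataFrame:
        """Return a copy of ``soils`` with missing ``SOIL_FEATURES`` filled."""
        self._check_fitted()
        out = soils.copy()
        x = out[SOIL_FEATURES].astype(float).to_numpy()
        all_missing = np.isnan(x).all(axis=1)
        if all_missing.any():
            raise DataError(
                f"{int(all_missing.sum())} soil(s) have all six properties missing"
            )
        span = self.hi_ - self.lo_
        filled = self._knn.transform((x - self.lo_) / span) * span + self.lo_
        # only missing cells are replaced; observed values pass through exactly
        x = np.where(np.isnan(x), filled, x)
        out[SOIL_FEATURES] = x
        return out

    def impute_soils(self, soils: Sequence[SoilSample]) -> list[SoilSample]:
        """Fill missing fields of :class:`SoilSample` objects.

        Marks filled fields in ``imputed_fields`` and renormalizes textures
        to 100% afterwards.
        """
        self._check_fitted()
        df = pd.DataFrame(
            [{f: getattr(s, f) for f in SOIL_FEATURES} for s in soils],
            dtype=float,
        )
        filled = self.transform(df)
        out: list[SoilSample] = []
        for soil, (_, row) in zip(soils, filled.iterrows()):
            missing = soil.missing_fields
            new = SoilSample(
                id=soil.id, fe=soil.fe, al=soil.al,
                imputed_fields=set(soil.imputed_fields) | set(missing),
                **{f: float(row[f]) for f in SOIL_FEATURES},
            )
            new.normalize_texture(tolerance=np.inf)
            out.append(new)
        return out

    def to_json(self, path: str | Path) -> None:
        self._check_fitted()
        bundle = {
            "k": self.k,
            "features": SOIL_FEATURES,
            "bounds": {"lo": self.lo_.tolist(), "hi": self.hi_.tolist()},
            "reference": self.reference_.tolist(),
        }
        Path(path).write_text(json.dumps(bundle))

    @classmethod
    def from_json(cls, path: str | Path) -> "SoilImputer":
        bundle = json.loads(Path(path).read_text())
        ref = pd.DataFrame(bundle["reference"], columns=bundle["features"])
        return cls().fit(ref, k=bundle["k"])
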