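"""The PFAS Sorption Stacking Model (PSSM).

A two-layer stacking ensemble predicting log10 Kd [L/kg] from nine features:
three compound descriptors evaluated at the soil's pH (effective molecular
weight, log KOW, charge density) and six soil properties (pH, CEC, Corg,
sand, silt, clay).

Layer one holds four base regressors -- ridge regression, random forest,
extremely randomized trees, and gradient boosting -- fitted on min-max-scaled
features.  Layer two is a small multi-layer perceptron that combines the four
base predictions into the final estimate.  By default the meta-model is
trained on out-of-fold base predictions (internal 5-fold CV) so that it never
sees a base learner's in-sample fit of the target; the literal in-sample
variant is available via ``PSSMConfig.stacking = "insample"`` for comparison.

Features are scaled with bounds learned from the training split only; the
target is left unscaled.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .harmonize import SorptionEntry
from .metrics import EvaluationReport, evaluate
from .registry import CompoundRegistry
from .speciation import speciate

__all__ = [
    "FEATURES",
    "PSSMConfig",
    "ScalingBounds",
    "StackedModel",
    "assemble_features",
    "minmax_scale",
    "split_holdout",
    "fit_pssm",
    "ablate",
    "cv_nrmse",
]

#: Canonical feature order of the model.
FEATURES = [
    "mw_effective", "log_kow", "charge_density",
    "ph", "cec", "corg", "sand", "silt", "clay",
]

TARGET = "log_kd"


@dataclass
class PSSMConfig:
    """Hyperparameters of the stacking ensemble (all overridable via YAML)."""

    ridge_alpha: float = 1.0
    rf_n_estimators: int = 500
    et_n_estimators: int = 500
    gb_n_estimators: int = 500
    gb_learning_rate: float = 0.05
    gb_max_depth: int = 3
    mlp_hidden: int = 16
    mlp_max_iter: int = 2000
    cv_folds: int = 5
    test_fraction: float = 0.2
    stacking: str = "oof"  # "oof" | "insample"
    nrmse_normalizer: str = "range"
    min_train: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PSSMConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def assemble_features(
    entries: Sequence[SorptionEntry],
    registry: CompoundRegistry,
) -> pd.DataFrame:
    """Build the model matrix: one row per entry, ``FEATURES`` + target.

    The compound is speciated at the entry's soil pH to obtain the effective
    molecular weight and charge density.  Soils must be complete
    (post-imputation).
    """
    rows = []
    for e in entries:
        missing = e.soil.missing_fields
        if missing:
            raise ValueError(f"entry {e.entry_id}: soil fields missing {missing}; impute first")
        compound = registry.get(e.compound_id)
        state = speciate(compound, e.soil.ph)
        rows.append({
            "entry_id": e.entry_id,
            "compound_id": compound.id,
            "mw_effective": state.mw_effective,
            "log_kow": compound.log_kow,
            "charge_density": state.charge_density,
            "ph": e.soil.ph, "cec": e.soil.cec, "corg": e.soil.corg,
            "sand": e.soil.sand, "silt": e.soil.silt, "clay": e.soil.clay,
            TARGET: e.log_kd,
            "outlier": e.outlier,
        })
    df = pd.DataFrame(rows)
    if not np.isfinite(df[FEATURES + [TARGET]].to_numpy()).all():
        raise ValueError("non-finite feature or target values")
    return df


@dataclass
class ScalingBounds:
    """Per-feature min/max learned from training data."""

    features: list[str]
    lo: dict[str, float]
    hi: dict[str, float]

    def transform(self, df: pd.DataFrame, warn: bool = True) -> np.ndarray:
        x = df[self.features].to_numpy(dtype=float)
        lo = np.array([self.lo[f] for f in self.features])
        hi = np.array([self.hi[f] for f in self.features])
        scaled = (x - lo) / (hi - lo)
        if warn and ((scaled < 0) | (scaled > 1)).any():
            outside = [f for j, f in enumerate(self.features)
                       if ((scaled[:, j] < 0) | (scaled[:, j] > 1)).any()]
            warnings.warn(
                f"values outside training bounds for {outside}; extrapolating",
                stacklevel=2,
            )
        return scaled

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        lo = np.array([self.lo[f] for f in self.features])
        hi = np.array([self.hi[f] for f in self.features])
        return scaled * (hi - lo) + lo


def minmax_scale(
    df: pd.DataFrame,
    bounds: ScalingBounds | None = None,
    features: Sequence[str] | None = None,
) -> tuple[np.ndarray, ScalingBounds]:
    """Min-max scale ``features`` of ``df``; fit bounds if not given."""
    features = list(features if features is not None else FEATURES)
    if bounds is None:
        lo = df[features].min()
        hi = df[features].max()
        constant = [f for f in features if hi[f] - lo[f] <= 0]
        if constant:
            raise ValueError(f"constant feature column(s): {constant}")
        bounds = ScalingBounds(features, lo.to_dict(), hi.to_dict())
    return bounds.transform(df), bounds


def split_holdout(
    df: pd.DataFrame, fraction: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed-reproducible random holdout split; test share uses floor(n * fraction)."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if len(df) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    n_test = int(len(df) * fraction)
    perm = rng.permutation(len(df))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return df.iloc[train_idx].copy(), df.iloc[test_idx].copy()


def _base_learners(config: PSSMConfig, seed: int) -> dict:
    return {
        "ridge": Ridge(alpha=config.ridge_alpha),
        "random_forest": RandomForestRegressor(
            n_estimators=config.rf_n_estimators, random_state=seed, n_jobs=1
        ),
        "extra_trees": ExtraTreesRegressor(
            n_estimators=config.et_n_estimators, random_state=seed + 1, n_jobs=1
        ),
        "gradient_boosting": GradientBoostingRegressor(
            n_estimators=config.gb_n_estimators,
            learning_rate=config.gb_learning_rate,
            max_depth=config.gb_max_depth,
            random_state=seed + 2,
        ),
    }


class StackedModel:
    """Fitted two-layer stacking ensemble.  Build with :func:`fit_pssm`."""

    def __init__(self, config: PSSMConfig, seed: int, features: Sequence[str] | None = None):
        self.config = config
        self.seed = seed
        self.features = list(features if features is not None else FEATURES)
        self.bounds: ScalingBounds | None = None
        self.learners: dict | None = None
        self.meta = None
        self.constant_: float | None = None
        self.manifest: dict = {}

    # -- fitting ------------------------------------------------------------

    def fit(self, train: pd.DataFrame) -> "StackedModel":
        if len(train) < self.config.min_train:
            raise ValueError(
                f"need >= {self.config.min_train} training entries, got {len(train)}"
            )
        y = train[TARGET].to_numpy(dtype=float)
        if not np.isfinite(y).all():
            raise ValueError("non-finite target values")
        x_scaled, self.bounds = minmax_scale(train, features=self.features)
        self.manifest = {
            "n_train": int(len(train)),
            "features": self.features,
            "seed": self.seed,
            "feature_ranges": {f: [self.bounds.lo[f], self.bounds.hi[f]]
                               for f in self.features},
        }
        if np.ptp(y) == 0:
            # degenerate training target: nothing to learn
            self.constant_ = float(y[0])
            return self

        self.learners = _base_learners(self.config, self.seed)
        if self.config.stacking == "oof":
            z = np.empty((len(train), len(self.learners)))
            folds = KFold(self.config.cv_folds, shuffle=True, random_state=self.seed)
            for tr, va in folds.split(x_scaled):
                fold_learners = _base_learners(self.config, self.seed)
                for m, (name, learner) in enumerate(fold_learners.items()):
                    learner.fit(x_scaled[tr], y[tr])
                    z[va, m] = learner.predict(x_scaled[va])
        elif self.config.stacking == "insample":
            for learner in self.learners.values():
                learner.fit(x_scaled, y)
            z = np.column_stack([l.predict(x_scaled) for l in self.learners.values()])
        else:
            raise ValueError(f"unknown stacking mode {self.config.stacking!r}")

        self.meta = MLPRegressor(
            hidden_layer_sizes=(self.config.mlp_hidden,),
            activation="relu",
            max_iter=self.config.mlp_max_iter,
            random_state=self.seed,
        )
        self.meta.fit(z, y)
        # final base learners are refit on the full training split
        for learner in self.learners.values():
            learner.fit(x_scaled, y)
        return self

    # -- prediction ---------------------------------------------------------

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Predict log10 Kd for a feature table (``FEATURES`` columns)."""
        if self.bounds is None:
            raise RuntimeError("model is not fitted")
        missing = [f for f in self.features if f not in features.columns]
        if missing:
            raise ValueError(f"feature columns missing: {missing}")
        if self.constant_ is not None:
            return np.full(len(features), self.constant_)
        x_scaled = self.bounds.transform(features)
        z = np.column_stack([l.predict(x_scaled) for l in self.learners.values()])
        return self.meta.predict(z)

    def predict_kd(self, features: pd.DataFrame) -> np.ndarray:
        """Kd [L/kg] = 10 ** log10 Kd."""
        return 10.0 ** self.predict(features)

    def out_of_domain(self, features: pd.DataFrame) -> np.ndarray:
        """Boolean mask of rows outside the training applicability ranges."""
        if self.bounds is None:
            raise RuntimeError("model is not fitted")
        scaled = self.bounds.transform(features, warn=False)
        return ((scaled < 0) | (scaled > 1)).any(axis=1)

    # -- persistence ----------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": asdict(self.config),
            "seed": self.seed,
            "features": self.features,
            "bounds": asdict(self.bounds) if self.bounds else None,
            "constant": self.constant_,
            "manifest": self.manifest,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
        if self.constant_ is None and self.learners is not None:
            joblib.dump({"learners": self.learners, "meta": self.meta}, d / "learners.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "StackedModel":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        model = cls(PSSMConfig(**manifest["config"]), manifest["seed"],
                    features=manifest.get("features"))
        if manifest["bounds"]:
            model.bounds = ScalingBounds(**manifest["bounds"])
        model.constant_ = manifest["constant"]
        model.manifest = manifest["manifest"]
        if model.constant_ is None:
            blob = joblib.load(d / "learners.joblib")
            model.learners, model.meta = blob["learners"], blob["meta"]
        return model


def fit_pssm(
    train: pd.DataFrame, seed: int = 0, config: PSSMConfig | None = None
) -> StackedModel:
    """Fit the stacking ensemble on a training feature table."""
    return StackedModel(config or PSSMConfig(), seed).fit(train)


def ablate(
    dataset: pd.DataFrame,
    dropped_feature: str,
    seed: int = 0,
    config: PSSMConfig | None = None,
) -> EvaluationReport:
    """Refit without one feature on the identical split/seed; report test metrics."""
    if dropped_feature not in FEATURES:
        raise ValueError(f"unknown feature {dropped_feature!r}")
    config = config or PSSMConfig()
    train, test = split_holdout(dataset, config.test_fraction, seed)
    kept = [f for f in FEATURES if f != dropped_feature]
    model = StackedModel(config, seed, features=kept).fit(train)
    pred = model.predict(test)
    return evaluate(test[TARGET], pred, normalizer=config.nrmse_normalizer,
                    corg=test["corg"] if "corg" in test else None)


def cv_nrmse(
    dataset: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    config: PSSMConfig | None = None,
) -> float:
    """k-fold cross-validated NRMSE: the full stack is refit per fold."""
    config = config or PSSMConfig()
    folds = KFold(k, shuffle=True, random_state=seed)
    scores = []
    for tr, va in folds.split(dataset):
        model = fit_pssm(dataset.iloc[tr], seed, config)
        pred = model.predict(dataset.iloc[va])
        scores.append(evaluate(dataset.iloc[va][TARGET], pred,
                               normalizer=config.nrmse_normalizer).nrmse)
    return float(np.mean(scores))
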