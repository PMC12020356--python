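"""Model-agnostic sensitivity analysis: exact Shapley values and partial dependence.

Shapley attribution treats the prediction as the payout of a cooperative game
among features.  The value of a coalition S is the interventional expectation

    v(S) = E_b[ f(x_S, b_{F\\S}) ],

i.e. features outside S are drawn from a background sample and predictions
averaged.  The attribution of feature i is the exact weighted sum over every
subset S of F\\{i}:

    phi_i = sum_S |S|! (|F|-|S|-1)! / |F|!  * ( v(S u {i}) - v(S) ).

With the model's nine features there are 2^9 = 512 coalitions, so the sum is
enumerated exactly -- no sampling approximation -- and local accuracy
(sum_i phi_i + v(empty) = f(x)) holds to floating-point precision.

Partial dependence of feature j is the mean prediction with that feature
pinned to a grid value while the remaining columns keep each observation's
values: PD(x_j) = (1/n) sum_i f(x_j, x_{i, -j}).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ShapResult", "PDResult", "shapley_exact", "partial_dependence"]

MAX_ENUMERATED_FEATURES = 12


@dataclass
class ShapResult:
    """Per-sample, per-feature Shapley attributions.

    ``values[s, i]`` is phi_i for sample s; ``base_value`` is the mean
    background prediction; ``ranking`` orders features by mean |phi|.
    """

    feature_names: list[str]
    values: np.ndarray
    base_value: float
    predictions: np.ndarray

    @property
    def ranking(self) -> list[str]:
        order = np.argsort(-np.abs(self.values).mean(axis=0))
        return [self.feature_names[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        """Long format: sample_id, feature, phi."""
        n, d = self.values.shape
        return pd.DataFrame({
            "sample_id": np.repeat(np.arange(n), d),
            "feature": np.tile(self.feature_names, n),
            "phi": self.values.ravel(),
        })


@dataclass
class PDResult:
    feature: str
    grid: np.ndarray
    pd_values: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature, "grid": self.grid,
                             "pd": self.pd_values})


def _as_predictor(model) -> Callable[[pd.DataFrame], np.ndarray]:
    predict = model.predict if hasattr(model, "predict") else model
    return lambda df: np.asarray(predict(df), dtype=float)


def _as_frame(x, feature_names: Sequence[str] | None) -> pd.DataFrame:
    if isinstance(x, pd.DataFrame):
        return x.reset_index(drop=True)
    x = np.asarray(x, dtype=float)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(x.shape[1])]
    return pd.DataFrame(x, columns=list(feature_names))


def shapley_exact(
    model,
    samples,
    background,
    feature_names: Sequence[str] | None = None,
) -> ShapResult:
    """Exact Shapley values by full subset enumeration.

    ``model`` is a fitted object with ``predict`` (or a callable); ``samples``
    the rows to explain; ``background`` the reference sample defining the
    interventional expectation.  Feature count is capped at
    ``MAX_ENUMERATED_FEATURES`` (2^d coalition evaluations).
    """
    predict = _as_predictor(model)
    xs = _as_frame(samples, feature_names)
    bg = _as_frame(background, feature_names)
    if list(bg.columns) != list(xs.columns):
        raise ValueError("samples and background must share feature columns")
    if len(bg) == 0:
        raise ValueError("background must be non-empty")
    d = xs.shape[1]
    if d > MAX_ENUMERATED_FEATURES:
        raise ValueError(
            f"{d} features exceeds the exact-enumeration cap of "
            f"{MAX_ENUMERATED_FEATURES}; use a sampling approximation instead"
        )
    names = list(xs.columns)
    n_bg = len(bg)
    n_masks = 1 << d
    weights = np.array(
        [factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)]
    )
    bg_arr = bg.to_numpy(dtype=float)

    values = np.zeros((len(xs), d))
    predictions = np.empty(len(xs))
    base_value = float(predict(bg).mean())
    for s_idx in range(len(xs)):
        x = xs.iloc[s_idx].to_numpy(dtype=float)
        # v(S) for every coalition, one batched predict call
        tiled = np.tile(bg_arr, (n_masks, 1))
        for mask in range(n_masks):
            block = tiled[mask * n_bg:(mask + 1) * n_bg]
            for j in range(d):
                if mask >> j & 1:
                    block[:, j] = x[j]
        preds = predict(pd.DataFrame(tiled, columns=names))
        v = preds.reshape(n_masks, n_bg).mean(axis=1)
        predictions[s_idx] = v[n_masks - 1]
        for j in range(d):
            bit = 1 << j
            for mask in range(n_masks):
                if not mask & bit:
                    size = int.bit_count(mask)
                    values[s_idx, j] += weights[size] * (v[mask | bit] - v[mask])
    return ShapResult(feature_names=names, values=values,
                      base_value=base_value, predictions=predictions)


def partial_dependence(
    model,
    feature: str,
    samples,
    grid: Sequence[float] | None = None,
    n_grid: int = 20,
    feature_names: Sequence[str] | None = None,
) -> PDResult:
    """Partial dependence of ``feature`` over ``grid`` (default: the observed
    range of the feature in ``samples``, ``n_grid`` evenly spaced points)."""
    predict = _as_predictor(model)
    xs = _as_frame(samples, feature_names)
    if len(xs) == 0:
        raise ValueError("empty sample set")
    if feature not in xs.columns:
        raise ValueError(f"unknown feature {feature!r}")
    if grid is None:
        col = xs[feature].to_numpy(dtype=float)
        grid = np.linspace(col.min(), col.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    pd_values = np.empty(len(grid))
    for g_idx, value in enumerate(grid):
        pinned = xs.copy()
        pinned[feature] = value
        pd_values[g_idx] = float(predict(pinned).mean())
    return PDResult(feature=feature, grid=grid, pd_values=pd_values, n=len(xs))
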