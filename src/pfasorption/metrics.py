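"""Evaluation statistics for log Kd predictions.

RMSE is the root mean squared error of predicted vs observed log Kd.  It is
reported normalized (NRMSE); the default normalizer is the observed range,
with mean and standard deviation available as alternatives:

    NRMSE = RMSE / (max(o) - min(o))        (normalizer="range")
    RPD   = sd(o) / RMSE                    (sample SD, n-1)

RPD (ratio of performance to deviation) above ~2 is conventionally read as a
usable model and above ~3 as an excellent one.  The report also carries the
OLS regression of predicted on observed (slope, intercept, r^2) and residual
diagnostics (mean, sample SD, adjusted Fisher skewness), optionally
stratified by organic-carbon bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["EvaluationReport", "evaluate"]

_CORG_BANDS = [(0.0, 1.0), (1.0, 2.0), (2.0, 5.0), (5.0, 100.0)]


@dataclass
class EvaluationReport:
    nrmse: float
    rmse: float
    rpd: float
    slope: float
    intercept: float
    r2: float
    residual_mean: float
    residual_sd: float
    residual_skewness: float
    n: int
    normalizer: str = "range"
    cv_nrmse: float | None = None
    corg_band_residuals: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    def to_text(self) -> str:
        lines = [
            f"n                  {self.n}",
            f"NRMSE ({self.normalizer:>5})      {self.nrmse:.4f}",
            f"RMSE               {self.rmse:.4f}",
            f"RPD                {self.rpd:.3f}",
            f"slope / intercept  {self.slope:.3f} / {self.intercept:.3f}",
            f"r2                 {self.r2:.3f}",
            f"residual mean/sd   {self.residual_mean:+.4f} / {self.residual_sd:.4f}",
            f"residual skewness  {self.residual_skewness:+.3f}",
        ]
        if self.cv_nrmse is not None:
            lines.append(f"CV-NRMSE           {self.cv_nrmse:.4f}")
        for band, r in self.corg_band_residuals.items():
            lines.append(f"  Corg {band:>8}%  mean {r['mean']:+.3f}  sd {r['sd']:.3f}  n {int(r['n'])}")
        return "\n".join(lines)


def evaluate(
    observed: Sequence[float],
    predicted: Sequence[float],
    normalizer: str = "range",
    corg: Sequence[float] | None = None,
    cv_nrmse: float | None = None,
) -> EvaluationReport:
    """Compute the evaluation report for observed vs predicted log Kd.

    ``cv_nrmse`` is passed through: cross-validated NRMSE is an average over
    refits the caller performs (see ``model.cv_nrmse``).
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1 or o.size < 2:
        raise ValueError("observed/predicted must be equal-length vectors, n >= 2")
    if np.ptp(o) == 0:
        raise ValueError("observed values are constant; NRMSE and RPD undefined")

    residuals = o - p
    rmse = float(np.sqrt(np.mean(residuals**2)))
    norms = {"range": float(np.ptp(o)), "mean": float(np.mean(o)), "sd": float(np.std(o, ddof=1))}
    if normalizer not in norms:
        raise ValueError(f"normalizer must be one of {sorted(norms)}")
    sd_o = norms["sd"]
    fit = stats.linregress(o, p)

    bands: dict[str, dict[str, float]] = {}
    if corg is not None:
        c = np.asarray(corg, dtype=float)
        for lo, hi in _CORG_BANDS:
            mask = (c >= lo) & (c < hi)
            if mask.sum() >= 2:
                r = residuals[mask]
                bands[f"{lo:g}-{hi:g}"] = {
                    "mean": float(np.mean(r)), "sd": float(np.std(r, ddof=1)),
                    "n": int(mask.sum()),
                }

    return EvaluationReport(
        nrmse=rmse / norms[normalizer] if rmse > 0 or norms[normalizer] != 0 else 0.0,
        rmse=rmse,
        rpd=sd_o / rmse if rmse > 0 else float("inf"),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        residual_mean=float(np.mean(residuals)),
        residual_sd=float(np.std(residuals, ddof=1)),
        residual_skewness=float(stats.skew(residuals, bias=False)) if np.std(residuals) > 0 else 0.0,
        n=int(o.size),
        normalizer=normalizer,
        cv_nrmse=cv_nrmse,
        corg_band_residuals=bands,
    )
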