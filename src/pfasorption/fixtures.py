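"""Synthetic data generators for offline testing and simulation studies.

Two generators make the full pipeline exercisable without any external data:

* :func:`gen_reference_soils` draws complete soil-property tables that mimic
  the structure of worldwide topsoil samples: organic carbon log-normal,
  skewed low (median < 2%), truncated to [0.03, 54]%; textures
  Dirichlet-distributed, summing to 100% with clay capped at 69%; pH normal
  around a Corg/clay-dependent center (organic soils acidic), truncated to
  [2.8, 9.0]; CEC built from Corg plus a clay term (its two real-world
  drivers), truncated to [0.1, 140] cmol+/kg.  The cross-correlations are
  what make KNN gap-filling of these properties meaningful.

* :func:`gen_sorption_dataset` samples compounds from the bundled registry
  and soils from the reference generator, computes the speciation-derived
  descriptors, and emits sorption entries whose latent target follows a known
  monotone rule

      log Kd = b0 + b1 log KOW + b2 log10(Corg) + b3 charge_density
               + b4 pH + compound offset + eps,    eps ~ N(0, sigma^2),

  so that parameter-recovery, sensitivity-direction and outlier-planting
  tests have an exact ground truth.  Soil-property gaps (pH, CEC, textures)
  are masked at a configurable rate to exercise the imputer; Corg is always
  reported, mirroring its near-universal availability in sorption studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .harmonize import SoilSample, SorptionEntry
from .registry import CompoundRegistry
from .speciation import speciate

__all__ = ["EffectSpec", "gen_reference_soils", "gen_sorption_dataset", "gen_grid_table"]


@dataclass
class EffectSpec:
    """Ground-truth rule for the synthetic log Kd.

    Default coefficients give hydrophobicity and organic carbon the dominant,
    positive roles, pH a weaker negative role and charge density a small
    positive one (more-negatively-charged species sorb less), with residual
    noise sigma = 0.3 log units -- the qualitative effect directions and
    magnitudes the sorption literature reports.
    """

    beta0: float = 0.2
    b_log_kow: float = 0.45
    b_log_corg: float = 0.55
    b_charge_density: float = 8.0e-4
    b_ph: float = -0.15
    sigma: float = 0.3
    #: compound id -> additive log-unit displacement (for outlier planting)
    outlier_offsets: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def gen_reference_soils(n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` complete synthetic soils (columns ph, cec, corg, sand, silt,
    clay, lat, lon); seed-reproducible."""
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)

    def trunc(draw, lo, hi, size):
        out = np.empty(size)
        todo = np.arange(size)
        while todo.size:
            vals = draw(todo.size)
            ok = (vals >= lo) & (vals <= hi)
            out[todo[ok]] = vals[ok]
            todo = todo[~ok]
        return out

    corg = trunc(lambda k: rng.lognormal(mean=0.0, sigma=1.1, size=k), 0.03, 54.0, n)

    # textures: Dirichlet scaled to 100 with the clay share capped at 69%
    texture = rng.dirichlet((2.4, 2.4, 1.2), size=n) * 100.0
    redo = texture[:, 2] > 69.0
    while redo.any():
        texture[redo] = rng.dirichlet((2.4, 2.4, 1.2), size=int(redo.sum())) * 100.0
        redo = texture[:, 2] > 69.0

    # pH couples to the other properties the way topsoil populations do:
    # organic soils run acidic, clay-rich soils less so
    ph_center = 6.3 - 1.2 * np.log10(corg) + 0.03 * (texture[:, 2] - 24.0)
    ph = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        vals = ph_center[todo] + rng.normal(0.0, 0.8, todo.size)
        ok = (vals >= 2.8) & (vals <= 9.0)
        ph[todo[ok]] = vals[ok]
        todo = todo[~ok]

    cec = np.clip(
        0.5 + 1.7 * corg + 0.12 * texture[:, 2] + rng.normal(0.0, 2.0, n),
        0.1, 140.0,
    )
    return pd.DataFrame({
        "ph": ph, "cec": cec, "corg": corg,
        "sand": texture[:, 0], "silt": texture[:, 1], "clay": texture[:, 2],
        "lat": rng.uniform(-60, 70, n), "lon": rng.uniform(-180, 180, n),
    })


def gen_sorption_dataset(
    n_entries: int,
    seed: int,
    effect: EffectSpec | None = None,
    registry: CompoundRegistry | None = None,
    compounds: list[str] | None = None,
    missing_rate: float = 0.15,
) -> tuple[list[SorptionEntry], pd.DataFrame]:
    """Generate sorption entries plus their noiseless ground truth.

    Returns ``(entries, truth)`` where ``truth`` has one row per entry with
    the generating features and the latent (noise-free) log Kd.  Soil gaps
    are masked in the entries only; ``truth`` keeps the complete values.
    """
    effect = effect or EffectSpec()
    effect.validate()
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    registry = registry or CompoundRegistry.bundled()
    pool = [registry.get(c) for c in compounds] if compounds else list(registry)

    rng = np.random.default_rng(seed)
    soils = gen_reference_soils(max(n_entries, 10), seed + 1).iloc[:n_entries]
    picks = rng.integers(0, len(pool), n_entries)
    noise = rng.normal(0.0, effect.sigma, n_entries)

    entries: list[SorptionEntry] = []
    truth_rows = []
    for i in range(n_entries):
        compound = pool[picks[i]]
        soil_row = soils.iloc[i]
        state = speciate(compound, soil_row["ph"])
        latent = (
            effect.beta0
            + effect.b_log_kow * compound.log_kow
            + effect.b_log_corg * np.log10(soil_row["corg"])
            + effect.b_charge_density * state.charge_density
            + effect.b_ph * soil_row["ph"]
            + effect.outlier_offsets.get(compound.id, 0.0)
        )
        log_kd = latent + noise[i]
        soil = SoilSample(
            id=f"syn{i}-soil",
            **{f: float(soil_row[f]) for f in ("ph", "cec", "corg", "sand", "silt", "clay")},
        )
        # mask soil-property gaps (Corg always reported)
        for fname in ("ph", "cec"):
            if rng.random() < missing_rate:
                setattr(soil, fname, None)
        if rng.random() < missing_rate:
            soil.sand = soil.silt = soil.clay = None
        entries.append(SorptionEntry(
            entry_id=f"syn{i}", compound_id=compound.id, soil=soil,
            kd=float(10.0 ** log_kd), source="direct", study_id="synthetic",
        ))
        truth_rows.append({
            "entry_id": f"syn{i}", "compound_id": compound.id,
            "log_kow": compound.log_kow, "charge_density": state.charge_density,
            "mw_effective": state.mw_effective,
            **{f: float(soil_row[f]) for f in ("ph", "cec", "corg", "sand", "silt", "clay")},
            "latent_log_kd": float(latent), "log_kd": float(log_kd),
        })
    return entries, pd.DataFrame(truth_rows)


def gen_grid_table(n_cells: int, seed: int, missing_rate: float = 0.0) -> pd.DataFrame:
    """Synthetic soil-property grid (LUCAS-style tabular interface)."""
    grid = gen_reference_soils(max(n_cells, 10), seed).iloc[:n_cells].copy()
    if missing_rate > 0:
        rng = np.random.default_rng(seed + 7)
        for col in ("ph", "cec", "corg", "sand", "silt", "clay"):
            mask = rng.random(len(grid)) < missing_rate
            grid.loc[mask, col] = np.nan
    return grid[["lat", "lon", "ph", "cec", "corg", "sand", "silt", "clay"]]
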