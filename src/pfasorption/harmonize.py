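"""Harmonization of heterogeneous literature-style sorption records.

Turns raw batch-sorption records -- which may report Kd directly, an
organic-carbon-normalized KOC, or fitted isotherm parameters -- into a clean,
unit-consistent Kd dataset [L/kg], and flags suspect records.

Conversions
-----------
* ``Kd = KOC * fOC`` with ``fOC = Corg% / 100``.
* From isotherm fits, Kd is evaluated at an aqueous concentration of 10% of
  the compound's water solubility, ``Cw = 0.1 S``:
  Freundlich ``Cs = KF Cw^n``  =>  ``Kd = KF (0.1 S)^(n-1)``;
  Langmuir ``Cs = Qmax KL Cw / (1 + KL Cw)``  =>  ``Kd = Qmax KL / (1 + 0.1 KL S)``.
* When several sources coexist for one record the preference order is
  direct > from KOC > from isotherm.

Outlier screening replaces case-by-case judgment with two reproducible rules:
a compound-level screen on residuals of mean log KOC regressed on log KOW
(default threshold 2x the residual RMSE) and a within-compound screen on the
deviation of an entry's log KOC from the compound median (default 1.5 log
units).  Flags are advisory; dropping flagged entries is a separate step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import CompoundRegistry

__all__ = [
    "DataError",
    "SoilSample",
    "Isotherm",
    "SorptionEntry",
    "kd_from_koc",
    "kd_from_isotherm",
    "koc_of",
    "flag_outliers",
    "harmonize_dataset",
    "entries_to_frame",
    "frame_to_entries",
    "RAW_COLUMNS",
]

log = logging.getLogger(__name__)

#: Documented CSV header for raw and harmonized datasets.
RAW_COLUMNS = [
    "entry_id", "compound_id", "study_id", "ph", "cec", "corg",
    "sand", "silt", "clay", "fe", "al", "kd", "koc",
    "isotherm_model", "isotherm_p1", "isotherm_p2", "source", "outlier",
]

TEXTURE_TOLERANCE = 2.0  # acceptable deviation of sand+silt+clay from 100%


class DataError(ValueError):
    """A record violates the dataset acceptance rules."""


@dataclass
class SoilSample:
    """One soil or sediment, with the six model properties.

    Properties may be ``None`` (missing) before imputation; ``imputed_fields``
    records which were filled downstream.  Fe and Al contents are carried for
    provenance but unused by the model.
    """

    id: str
    ph: float | None = None
    cec: float | None = None
    corg: float | None = None
    sand: float | None = None
    silt: float | None = None
    clay: float | None = None
    fe: float | None = None
    al: float | None = None
    imputed_fields: set[str] = field(default_factory=set)

    def validate(self) -> None:
        if self.ph is not None and not 0 <= self.ph <= 14:
            raise DataError(f"soil {self.id}: ph {self.ph} outside [0, 14]")
        if self.cec is not None and self.cec < 0:
            raise DataError(f"soil {self.id}: negative CEC")
        for name in ("corg", "sand", "silt", "clay"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise DataError(f"soil {self.id}: {name}={v} outside [0, 100]%")
        self.normalize_texture()

    def normalize_texture(self, tolerance: float = TEXTURE_TOLERANCE) -> None:
        """Renormalize reported textures to exactly 100% if within tolerance."""
        parts = (self.sand, self.silt, self.clay)
        if any(p is None for p in parts):
            return
        total = sum(parts)
        if abs(total - 100.0) > tolerance:
            raise DataError(
                f"soil {self.id}: textures sum to {total:.1f}%, outside 100 +/- {tolerance}%"
            )
        self.sand, self.silt, self.clay = (100.0 * p / total for p in parts)

    @property
    def missing_fields(self) -> list[str]:
        return [f for f in ("ph", "cec", "corg", "sand", "silt", "clay")
                if getattr(self, f) is None]


@dataclass(frozen=True)
class Isotherm:
    """Fitted sorption isotherm: Freundlich (KF, n) or Langmuir (Qmax, KL)."""

    model: Literal["freundlich", "langmuir"]
    p1: float  # KF [L/kg * (mg/L)^(1-n)] or Qmax [mg/kg]
    p2: float  # n [-] or KL [L/mg]

    def __post_init__(self) -> None:
        if self.model not in ("freundlich", "langmuir"):
            raise DataError(f"unknown isotherm model {self.model!r}")
        if self.p1 <= 0 or self.p2 <= 0:
            raise DataError(f"isotherm parameters must be positive: {self}")


@dataclass
class SorptionEntry:
    """One harmonized soil/compound sorption record with provenance."""

    entry_id: str
    compound_id: str
    soil: SoilSample
    kd: float
    source: Literal["direct", "from_koc", "from_isotherm"]
    study_id: str = ""
    koc: float | None = None
    isotherm: Isotherm | None = None
    outlier: bool = False
    outlier_reason: str | None = None

    def __post_init__(self) -> None:
        if not (self.kd > 0 and math.isfinite(self.kd)):
            raise DataError(f"entry {self.entry_id}: kd must be positive, got {self.kd}")
        if self.source == "from_koc" and (self.koc is None or self.soil.corg is None):
            raise DataError(f"entry {self.entry_id}: from_koc requires koc and corg")

    @property
    def log_kd(self) -> float:
        return math.log10(self.kd)


def kd_from_koc(koc: float, corg: float) -> float:
    """Kd [L/kg] from KOC [L/kg OC] and organic carbon content [%]."""
    if koc <= 0:
        raise DataError(f"koc must be positive, got {koc}")
    if corg is None or corg <= 0:
        raise DataError("conversion from KOC undefined for corg <= 0")
    return koc * corg / 100.0


def kd_from_isotherm(isotherm: Isotherm, solubility: float) -> float:
    """Kd = Cs/Cw evaluated at Cw = 10% of the compound's water solubility."""
    if solubility is None or solubility <= 0:
        raise DataError("isotherm conversion requires a positive solubility")
    cw = 0.1 * solubility
    if isotherm.model == "freundlich":
        return isotherm.p1 * cw ** (isotherm.p2 - 1.0)
    return isotherm.p1 * isotherm.p2 / (1.0 + isotherm.p2 * cw)


def koc_of(entry: SorptionEntry) -> float:
    """Organic-carbon-normalized KOC = Kd / fOC [L/kg OC]."""
    if entry.soil.corg is None or entry.soil.corg <= 0:
        raise DataError(f"entry {entry.entry_id}: KOC undefined for corg <= 0")
    return entry.kd / (entry.soil.corg / 100.0)


def flag_outliers(
    entries: Sequence[SorptionEntry],
    registry: CompoundRegistry,
    compound_rmse_factor: float = 2.0,
    entry_threshold: float = 1.5,
) -> tuple[list[SorptionEntry], dict]:
    """Advisory outlier flags at the compound and entry level.

    Compound screen: OLS of per-compound mean log KOC on log KOW; compounds
    whose absolute residual exceeds ``compound_rmse_factor`` times the
    residual RMSE are flagged.  Entry screen: entries whose log KOC deviates
    from the compound median by more than ``entry_threshold`` log units.

    Returns new entries (inputs untouched) plus a diagnostics dict.
    """
    usable = [e for e in entries if e.soil.corg is not None and e.soil.corg > 0]
    by_compound: dict[str, list[float]] = {}
    for e in usable:
        by_compound.setdefault(e.compound_id, []).append(math.log10(koc_of(e)))
    if len(by_compound) < 3:
        raise DataError("outlier screening needs >= 3 compounds with KOC data")

    cids = sorted(by_compound)
    mean_log_koc = np.array([np.mean(by_compound[c]) for c in cids])
    log_kow = np.array([registry.get(c).log_kow for c in cids])
    fit = stats.linregress(log_kow, mean_log_koc)
    residuals = mean_log_koc - (fit.slope * log_kow + fit.intercept)
    rmse = float(np.sqrt(np.mean(residuals**2)))
    threshold = compound_rmse_factor * rmse
    # an (effectively) exact fit has no outliers; guard against epsilon RMSE
    flagged_compounds = {
        c for c, r in zip(cids, residuals) if rmse > 1e-9 and abs(r) > threshold
    }

    medians = {c: float(np.median(v)) for c, v in by_compound.items()}
    out: list[SorptionEntry] = []
    flagged_entries = []
    for e in entries:
        reason = None
        if e.compound_id in flagged_compounds:
            reason = "compound_koc_kow_residual"
        elif e.soil.corg is not None and e.soil.corg > 0:
            dev = abs(math.log10(koc_of(e)) - medians.get(e.compound_id, np.nan))
            if np.isfinite(dev) and dev > entry_threshold:
                reason = "entry_koc_median_deviation"
        if reason:
            flagged_entries.append(e.entry_id)
            out.append(replace(e, outlier=True, outlier_reason=reason))
        else:
            out.append(replace(e, outlier=False, outlier_reason=None))

    diagnostics = {
        "regression": {"slope": fit.slope, "intercept": fit.intercept,
                       "r2": fit.rvalue**2, "rmse": rmse},
        "residuals": dict(zip(cids, residuals.tolist())),
        "threshold": threshold,
        "flagged_compounds": sorted(flagged_compounds),
        "flagged_entries": flagged_entries,
    }
    return out, diagnostics


def _get(row: dict, key: str) -> float | None:
    v = row.get(key)
    if v is None or (isinstance(v, str) and not v.strip()):
        return None
    v = float(v)
    return None if math.isnan(v) else v


def harmonize_dataset(
    raw: pd.DataFrame,
    registry: CompoundRegistry,
    screen_outliers: bool = True,
) -> tuple[list[SorptionEntry], dict]:
    """Build harmonized entries from a raw records table (``RAW_COLUMNS`` schema).

    Each row must yield a Kd by one of the accepted routes; rows that cannot
    (unknown compound, corg missing for a KOC record, solubility missing for
    an isotherm record, broken textures) are rejected with a reason code
    collected in the report.
    """
    entries: list[SorptionEntry] = []
    rejected: list[dict] = []
    for idx, row in enumerate(raw.to_dict(orient="records")):
        entry_id = str(row.get("entry_id") or f"row{idx}")
        try:
            cid = str(row["compound_id"])
            compound = registry.get(cid)
            soil = SoilSample(
                id=f"{entry_id}-soil",
                ph=_get(row, "ph"), cec=_get(row, "cec"), corg=_get(row, "corg"),
                sand=_get(row, "sand"), silt=_get(row, "silt"), clay=_get(row, "clay"),
                fe=_get(row, "fe"), al=_get(row, "al"),
            )
            soil.validate()
            kd, koc, iso = _get(row, "kd"), _get(row, "koc"), None
            model = row.get("isotherm_model")
            if isinstance(model, str) and model.strip():
                iso = Isotherm(model.strip().lower(), _get(row, "isotherm_p1"),
                               _get(row, "isotherm_p2"))
            if kd is not None:
                source = "direct"
            elif koc is not None:
                kd, source = kd_from_koc(koc, soil.corg), "from_koc"
            elif iso is not None:
                kd, source = kd_from_isotherm(iso, compound.solubility), "from_isotherm"
            else:
                raise DataError(f"entry {entry_id}: no Kd, KOC or isotherm reported")
            entries.append(SorptionEntry(
                entry_id=entry_id, compound_id=compound.id, soil=soil, kd=kd,
                source=source, study_id=str(row.get("study_id") or ""),
                koc=koc, isotherm=iso,
            ))
        except (DataError, KeyError, ValueError) as err:
            log.warning("rejected %s: %s", entry_id, err)
            rejected.append({"entry_id": entry_id, "reason": str(err)})

    report: dict = {"n_raw": len(raw), "n_accepted": len(entries), "rejected": rejected,
                    "n_by_source": pd.Series([e.source for e in entries])
                    .value_counts().to_dict() if entries else {}}
    if screen_outliers and entries:
        entries, diag = flag_outliers(entries, registry)
        report["outliers"] = diag
    return entries, report


def entries_to_frame(entries: Iterable[SorptionEntry]) -> pd.DataFrame:
    """Serialize entries to the documented CSV schema (plus log_kd)."""
    rows = []
    for e in entries:
        rows.append({
            "entry_id": e.entry_id, "compound_id": e.compound_id,
            "study_id": e.study_id, "ph": e.soil.ph, "cec": e.soil.cec,
            "corg": e.soil.corg, "sand": e.soil.sand, "silt": e.soil.silt,
            "clay": e.soil.clay, "fe": e.soil.fe, "al": e.soil.al,
            "kd": e.kd, "log_kd": e.log_kd, "koc": e.koc,
            "isotherm_model": e.isotherm.model if e.isotherm else None,
            "isotherm_p1": e.isotherm.p1 if e.isotherm else None,
            "isotherm_p2": e.isotherm.p2 if e.isotherm else None,
            "source": e.source, "outlier": e.outlier,
            "outlier_reason": e.outlier_reason,
        })
    return pd.DataFrame(rows)


def frame_to_entries(df: pd.DataFrame) -> list[SorptionEntry]:
    """Rebuild entries from a harmonized table written by :func:`entries_to_frame`."""
    entries = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        entry_id = str(row.get("entry_id") or f"row{idx}")
        iso = None
        model = row.get("isotherm_model")
        if isinstance(model, str) and model.strip():
            iso = Isotherm(model, float(row["isotherm_p1"]), float(row["isotherm_p2"]))
        soil = SoilSample(
            id=f"{entry_id}-soil",
            ph=_get(row, "ph"), cec=_get(row, "cec"), corg=_get(row, "corg"),
            sand=_get(row, "sand"), silt=_get(row, "silt"), clay=_get(row, "clay"),
            fe=_get(row, "fe"), al=_get(row, "al"),
        )
        entries.append(SorptionEntry(
            entry_id=entry_id, compound_id=str(row["compound_id"]), soil=soil,
            kd=float(row["kd"]), source=str(row.get("source") or "direct"),
            study_id=str(row.get("study_id") or ""), koc=_get(row, "koc"),
            isotherm=iso, outlier=bool(row.get("outlier", False)),
        ))
    return entries
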