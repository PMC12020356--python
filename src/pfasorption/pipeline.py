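"""End-to-end convenience glue: impute -> assemble -> split -> fit -> evaluate."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .harmonize import SorptionEntry
from .impute import SoilImputer
from .metrics import EvaluationReport, evaluate
from .model import PSSMConfig, StackedModel, assemble_features, fit_pssm, split_holdout
from .registry import CompoundRegistry

__all__ = ["PipelineResult", "train_and_evaluate"]


@dataclass
class PipelineResult:
    model: StackedModel
    report: EvaluationReport
    train: pd.DataFrame
    test: pd.DataFrame


def train_and_evaluate(
    entries: Sequence[SorptionEntry],
    registry: CompoundRegistry,
    reference_soils: pd.DataFrame | None = None,
    seed: int = 0,
    config: PSSMConfig | None = None,
    k_neighbors: int = 5,
    exclude_outliers: bool = True,
) -> PipelineResult:
    """Run the full modeling pipeline on harmonized entries.

    Missing soil properties are imputed from ``reference_soils`` (required if
    any gaps exist); outlier-flagged entries are dropped before the split.
    """
    config = config or PSSMConfig()
    if exclude_outliers:
        entries = [e for e in entries if not e.outlier]
    if any(e.soil.missing_fields for e in entries):
        if reference_soils is None:
            raise ValueError("entries have soil gaps but no reference table was given")
        imputer = SoilImputer(k=k_neighbors).fit(reference_soils)
        soils = imputer.impute_soils([e.soil for e in entries])
        for e, s in zip(entries, soils):
            e.soil = s
    dataset = assemble_features(entries, registry)
    train, test = split_holdout(dataset, config.test_fraction, seed)
    model = fit_pssm(train, seed, config)
    pred = model.predict(test)
    report = evaluate(
        test["log_kd"], pred, normalizer=config.nrmse_normalizer, corg=test["corg"]
    )
    return PipelineResult(model=model, report=report, train=train, test=test)
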