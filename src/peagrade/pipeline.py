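"""End-to-end orchestration of the three classification models.

* Model 1 — market grade from the four mid-wavelength colour factors,
  trained on non-defective calibration samples only (Yellow Forage is
  excluded: every Yellow Forage sample is defective).
* Model 2 — market grade from eight features (Model 1's colours plus
  violet factor, equivalent diameter, circularity, plumpness), trained on
  the full calibration set.
* Defect model — defective vs non-defective from the same eight
  features, trained on the full calibration set.

Each model is evaluated on four cells: non-defective / defective samples
of the calibration / validation splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import discriminant as da
from .features import (
    FEATURE_NAMES,
    SampleRecord,
    Standardiser,
    apply_standardiser,
    extract_seed_features,
    fit_standardiser,
    sample_features,
)
from .preprocess import DEFAULT_HEIGHT_THRESHOLD, build_masks
from .synth import GRADE_NAMES, Dataset, DatasetDesign, default_design, generate_dataset

__all__ = [
    "MODEL1_FEATURES",
    "MODEL2_FEATURES",
    "MODEL_IDS",
    "ModelConfig",
    "CellResult",
    "AccuracyReport",
    "model_config",
    "extract_records",
    "standardise_records",
    "run_model",
    "run_models",
    "run_pipeline",
    "report",
]

MODEL1_FEATURES = ("blue_factor", "green_factor", "orange_factor", "red_factor")
MODEL2_FEATURES = MODEL1_FEATURES + (
    "violet_factor",
    "equivalent_diameter",
    "circularity",
    "plumpness",
)
MODEL_IDS = ("model1", "model2", "defect")

#: Evaluation cells in report column order.
CELLS = (
    "nondefective_calibration",
    "defective_calibration",
    "nondefective_validation",
    "defective_validation",
)


@dataclass(frozen=True)
class ModelConfig:
    model_id: str
    feature_names: tuple[str, ...]
    class_labels: tuple[str, ...]
    target: str  # "grade" or "defect"
    train_on_defective: bool  # include defective calibration samples when fitting
    eval_cells: tuple[str, ...] = CELLS
    exclude_grades_from_defective_eval: tuple[str, ...] = ()


def model_config(model_id: str) -> ModelConfig:
    """Built-in configuration for one of the three models."""
    if model_id == "model1":
        labels = tuple(g for g in GRADE_NAMES if g != "Yellow Forage")
        return ModelConfig(
            model_id="model1",
            feature_names=MODEL1_FEATURES,
            class_labels=labels,
            target="grade",
            train_on_defective=False,
            # the paper's first model is never scored on defective
            # calibration samples (reported NA)
            eval_cells=(
                "nondefective_calibration",
                "nondefective_validation",
                "defective_validation",
            ),
            exclude_grades_from_defective_eval=("Yellow Forage",),
        )
    if model_id == "model2":
        return ModelConfig(
            model_id="model2",
            feature_names=MODEL2_FEATURES,
            class_labels=GRADE_NAMES,
            target="grade",
            train_on_defective=True,
        )
    if model_id == "defect":
        return ModelConfig(
            model_id="defect",
            feature_names=MODEL2_FEATURES,
            class_labels=da.DEFECT_LABELS,
            target="defect",
            train_on_defective=True,
        )
    raise ValueError(f"unknown model id {model_id!r}")


@dataclass(frozen=True)
class CellResult:
    n: int
    n_correct: int
    accuracy_pct: float
    confusion: pd.DataFrame  # rows = true labels, columns = predicted


@dataclass(frozen=True)
class AccuracyReport:
    model_id: str
    cells: dict[str, CellResult | None]

    def cell_pct(self, cell: str) -> float | None:
        res = self.cells.get(cell)
        return None if res is None else res.accuracy_pct


def extract_records(
    dataset: Dataset, height_threshold: float = DEFAULT_HEIGHT_THRESHOLD
) -> list[SampleRecord]:
    """Mask, measure and aggregate every sample of a dataset."""
    records = []
    for sample in dataset:
        feats = []
        for stack in sample.stacks:
            masks = build_masks(stack, height_threshold)
            feats.append(extract_seed_features(stack, masks))
        records.append(
            SampleRecord(
                sample_id=sample.sample_id,
                grade=sample.grade,
                split=sample.split,
                defective=sample.defective,
                raw_features=sample_features(feats),
            )
        )
    return records


def standardise_records(records: Sequence[SampleRecord]) -> Standardiser:
    """Fit the standardiser on the full calibration split, apply to all records."""
    calib = [r for r in records if r.split == "calibration"]
    std = fit_standardiser(calib)
    apply_standardiser(std, records)
    return std


def _cell_records(records: Sequence[SampleRecord], cell: str) -> list[SampleRecord]:
    defective = cell.startswith("defective")
    split = cell.split("_")[1]
    return [r for r in records if r.split == split and r.defective == defective]


def _evaluate_cell(
    model: da.LDAModel, records: Sequence[SampleRecord], target: str
) -> CellResult | None:
    if not records:
        return None
    preds = da.classify_records(model, records)
    true = [da.record_label(r, target) for r in records]
    pred = [p.predicted_label for p in preds]
    n_correct = sum(t == p for t, p in zip(true, pred))
    row_labels = sorted(set(true) | set(model.class_labels))
    confusion = pd.crosstab(
        pd.Series(true, name="true"), pd.Series(pred, name="predicted")
    ).reindex(index=row_labels, columns=list(model.class_labels), fill_value=0)
    return CellResult(
        n=len(records),
        n_correct=n_correct,
        accuracy_pct=100.0 * n_correct / len(records),
        confusion=confusion,
    )


def run_model(
    config: ModelConfig,
    records: Sequence[SampleRecord],
    forward_selection: bool = False,
) -> tuple[da.LDAModel, AccuracyReport]:
    """Fit one model on its configured training subset and score all cells.

    With ``forward_selection=True`` the configured feature list is treated
    as an ordered candidate list and greedily pruned on the training
    records before the final fit.
    """
    train = [r for r in records if r.split == "calibration"]
    if not config.train_on_defective:
        train = [r for r in train if not r.defective]
    present = {da.record_label(r, config.target) for r in train}
    missing = [c for c in config.class_labels if c not in present]
    if missing:
        raise ValueError(
            f"{config.model_id}: training subset is missing class(es) {missing}"
        )
    features = list(config.feature_names)
    if forward_selection:
        features = da.forward_select(train, features, config.class_labels, config.target)
    model = da.fit_lda(train, features, config.class_labels, config.target)

    cells: dict[str, CellResult | None] = {}
    for cell in CELLS:
        if cell not in config.eval_cells:
            cells[cell] = None
            continue
        cell_records = _cell_records(records, cell)
        if cell.startswith("defective") and config.exclude_grades_from_defective_eval:
            cell_records = [
                r for r in cell_records
                if r.grade not in config.exclude_grades_from_defective_eval
            ]
        cells[cell] = _evaluate_cell(model, cell_records, config.target)
    return model, AccuracyReport(model_id=config.model_id, cells=cells)


def run_models(
    records: Sequence[SampleRecord],
    model_ids: Sequence[str] = MODEL_IDS,
    forward_selection: bool = False,
) -> dict[str, tuple[da.LDAModel, AccuracyReport]]:
    return {
        mid: run_model(model_config(mid), records, forward_selection)
        for mid in model_ids
    }


def run_pipeline(
    design: DatasetDesign | None = None,
    seed: int | None = None,
    model_ids: Sequence[str] = MODEL_IDS,
    height_threshold: float = DEFAULT_HEIGHT_THRESHOLD,
):
    """Full chain: generate -> mask -> features -> standardise -> models.

    Returns ``(records, results)`` where results maps model id to
    ``(LDAModel, AccuracyReport)``.
    """
    if design is None:
        design = default_design()
    if seed is not None:
        from dataclasses import replace

        design = replace(design, rng_seed=seed)
    dataset = generate_dataset(design)
    records = extract_records(dataset, height_threshold)
    standardise_records(records)
    return records, run_models(records, model_ids)


_COLUMN_TITLES = {
    "nondefective_calibration": "NonDef Cal %",
    "defective_calibration": "Def Cal %",
    "nondefective_validation": "NonDef Val %",
    "defective_validation": "Def Val %",
}


def report(reports: Sequence[AccuracyReport]) -> str:
    """Format accuracy reports as a fixed-width table.

    One row per model, the four evaluation cells as columns (accuracies
    rounded to the nearest integer percent), NA for unscored cells.
    """
    if not reports:
        raise ValueError("no reports")
    header = ["Model".ljust(10)] + [_COLUMN_TITLES[c].rjust(14) for c in CELLS]
    lines = ["".join(header)]
    for rep in reports:
        row = [rep.model_id.ljust(10)]
        for cell in CELLS:
            pct = rep.cell_pct(cell)
            row.append(("NA" if pct is None else str(int(round(pct)))).rjust(14))
        lines.append("".join(row))
    return "\n".join(lines)
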