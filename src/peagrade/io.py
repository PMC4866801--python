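"""On-disk formats: image stacks, manifests, feature tables, models.

Stacks are stored as one 7-page 32-bit float TIFF per seed (page order
violet, blue, green, orange, red, NIR, height). Tables are TSV; the
standardiser is a small key-value text file and LDA models are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .discriminant import LDAModel, Prediction, record_label
from .features import FEATURE_NAMES, SampleRecord, Standardiser
from .synth import CellCount, Dataset, DatasetDesign, ImageStack, default_design

__all__ = [
    "write_stack",
    "read_stack",
    "write_dataset",
    "read_manifest",
    "records_to_frame",
    "write_features",
    "read_features",
    "write_standardiser",
    "read_standardiser",
    "model_to_json",
    "model_from_json",
    "write_predictions",
    "design_from_toml",
]


def write_stack(stack: ImageStack, path: str | Path) -> None:
    pages = np.concatenate([stack.intensity, stack.height[None]], axis=0)
    tifffile.imwrite(path, pages.astype(np.float32))


def read_stack(path: str | Path) -> ImageStack:
    pages = np.asarray(tifffile.imread(path), dtype=float)
    if pages.ndim != 3 or pages.shape[0] != 7:
        raise ValueError(f"{path}: expected a 7-page stack, got shape {pages.shape}")
    return ImageStack(intensity=pages[:6], height=pages[6])


def write_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write every stack as TIFF plus a manifest.tsv; returns manifest path."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in dataset:
        paths = []
        for k, stack in enumerate(sample.stacks):
            rel = f"images/{sample.sample_id}-s{k:03d}.tif"
            write_stack(stack, out_dir / rel)
            paths.append(rel)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "grade": sample.grade,
                "split": sample.split,
                "defective": int(sample.defective),
                "seed_image_paths": ";".join(paths),
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "grade", "split", "defective", "seed_image_paths"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def records_to_frame(records: Sequence[SampleRecord], standardised: bool = False) -> pd.DataFrame:
    rows = []
    for r in records:
        vec = r.std_features if standardised else r.raw_features
        row = {
            "sample_id": r.sample_id,
            "grade": r.grade,
            "split": r.split,
            "defective": int(r.defective),
        }
        row.update({name: vec[i] for i, name in enumerate(FEATURE_NAMES)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_features(records: Sequence[SampleRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_features(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return [
        SampleRecord(
            sample_id=row["sample_id"],
            grade=row["grade"],
            split=row["split"],
            defective=bool(row["defective"]),
            raw_features=np.array([row[n] for n in FEATURE_NAMES], dtype=float),
        )
        for _, row in df.iterrows()
    ]


def write_standardiser(std: Standardiser, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tmean\tsd\n")
        for i, name in enumerate(std.feature_names):
            fh.write(f"{name}\t{float(std.mean[i]):.17g}\t{float(std.sd[i]):.17g}\n")


def read_standardiser(path: str | Path) -> Standardiser:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    order = {n: i for i, n in enumerate(df["feature"])}
    idx = [order[n] for n in FEATURE_NAMES]
    return Standardiser(
        mean=df["mean"].to_numpy(float)[idx], sd=df["sd"].to_numpy(float)[idx]
    )


def model_to_json(model: LDAModel, path: str | Path | None = None) -> str:
    doc = {
        "feature_names": list(model.feature_names),
        "class_labels": list(model.class_labels),
        "class_means": model.class_means.tolist(),
        "pooled_cov": model.pooled_cov.tolist(),
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path) -> LDAModel:
    from scipy import linalg

    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    doc = json.loads(text)
    pooled = np.asarray(doc["pooled_cov"], dtype=float)
    cho = linalg.cho_factor(pooled)
    inv = linalg.cho_solve(cho, np.eye(pooled.shape[0]))
    return LDAModel(
        feature_names=tuple(doc["feature_names"]),
        class_labels=tuple(doc["class_labels"]),
        class_means=np.asarray(doc["class_means"], dtype=float),
        pooled_cov=pooled,
        pooled_cov_inv=inv,
        _cho=cho,
    )


def write_predictions(
    records: Sequence[SampleRecord],
    predictions: Sequence[Prediction],
    target: str,
    path: str | Path,
) -> None:
    rows = []
    for r, p in zip(records, predictions):
        row = {
            "sample_id": r.sample_id,
            "true_label": record_label(r, target),
            "predicted_label": p.predicted_label,
            "nearest_distance": p.nearest_distance,
        }
        row.update({f"d_{c}": d for c, d in p.distances.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def design_from_toml(path: str | Path, rng_seed: int | None = None) -> DatasetDesign:
    """Load a dataset design from TOML.

    Schema::

        seeds_per_sample = 30
        rng_seed = 0
        noise_sd = 0.05
        image_shape = [96, 96]
        [cells."White"]
        calibration = [50, 4]
        validation = [45, 4]

    Omitted cells fall back to the default design's cells.
    """
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    base = default_design()
    cells = dict(base.cells)
    if "cells" in doc:
        cells = {}
        for grade, splits in doc["cells"].items():
            for split, (total, defective) in splits.items():
                cells[(grade, split)] = CellCount(int(total), int(defective))
    kwargs = {}
    for key in (
        "seeds_per_sample",
        "rng_seed",
        "noise_sd",
        "reflect_jitter",
        "defective_seed_fraction",
    ):
        if key in doc:
            kwargs[key] = doc[key]
    if "image_shape" in doc:
        kwargs["image_shape"] = tuple(doc["image_shape"])
    if "severity_range" in doc:
        kwargs["severity_range"] = tuple(doc["severity_range"])
    if rng_seed is not None:
        kwargs["rng_seed"] = rng_seed
    return DatasetDesign(cells=cells, **kwargs)
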