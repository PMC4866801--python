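"""Single-seed feature extraction, sample aggregation, standardisation.

Thirteen features per seed: six height-corrected colour factors (one per
channel), median seed height, equivalent diameter, area, plumpness,
perimeter, volume and circularity. Per-sample feature values are the
coordinate-wise medians across the sample's seeds; sample vectors are
standardised to zero mean / unit standard deviation using parameters
fitted on the calibration set only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage import measure

from .preprocess import MaskPair
from .synth import CHANNELS, ImageStack

__all__ = [
    "FEATURE_NAMES",
    "COLOUR_FEATURES",
    "SIZE_FEATURES",
    "SHAPE_FEATURES",
    "SeedFeatures",
    "SampleRecord",
    "Standardiser",
    "colour_factors",
    "size_shape_features",
    "extract_seed_features",
    "sample_features",
    "fit_standardiser",
    "apply_standardiser",
]

#: Canonical feature order used in every 13-vector and output table.
FEATURE_NAMES = (
    "violet_factor",
    "blue_factor",
    "green_factor",
    "orange_factor",
    "red_factor",
    "nir_factor",
    "seed_height",
    "equivalent_diameter",
    "area",
    "plumpness",
    "perimeter",
    "volume",
    "circularity",
)

COLOUR_FEATURES = FEATURE_NAMES[:6]
SIZE_FEATURES = ("seed_height", "equivalent_diameter", "area", "volume")
SHAPE_FEATURES = ("plumpness", "perimeter", "circularity")


@dataclass(frozen=True)
class SeedFeatures:
    violet_factor: float
    blue_factor: float
    green_factor: float
    orange_factor: float
    red_factor: float
    nir_factor: float
    seed_height: float
    equivalent_diameter: float
    area: float
    plumpness: float
    perimeter: float
    volume: float
    circularity: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


@dataclass
class SampleRecord:
    """One sample: identity, labels, and its (raw / standardised) feature vector."""

    sample_id: str
    grade: str
    split: str
    defective: bool
    raw_features: np.ndarray
    std_features: np.ndarray | None = None

    def feature_vector(self, names: Sequence[str], standardised: bool = True) -> np.ndarray:
        src = self.std_features if standardised else self.raw_features
        if standardised and self.std_features is None:
            raise ValueError(f"record {self.sample_id} has no standardised features")
        idx = [FEATURE_NAMES.index(n) for n in names]
        return np.asarray(src, dtype=float)[idx]


def colour_factors(stack: ImageStack, m2: np.ndarray) -> np.ndarray:
    """Height-corrected colour factors, one per channel.

    Each in-mask pixel's intensity is divided by its height (removing the
    height-driven component of intensity); the factor is the median of
    the corrected values.
    """
    if not m2.any():
        raise ValueError("m2 is empty")
    h = stack.height[m2]
    if np.any(h <= 0):
        raise AssertionError("zero height inside m2; height threshold must be > 0")
    return np.array([np.median(stack.intensity[c][m2] / h) for c in range(len(CHANNELS))])


def size_shape_features(stack: ImageStack, masks: MaskPair) -> dict[str, float]:
    """Size and shape descriptors from the mask pair.

    * area: pixel count of m1
    * perimeter: length-weighted count of boundary pixels of m1
      (8-neighbour boundary test; diagonally adjacent boundary steps
      contribute sqrt(2))
    * equivalent diameter: diameter of the circle of equal area
    * volume: sum of heights over m1
    * seed height: median height over m2
    * circularity: (area * 4) / (equivalent diameter * perimeter)
    * plumpness: seed height / equivalent diameter
    """
    m1, m2 = masks.m1, masks.m2
    if not m1.any():
        raise ValueError("empty mask")
    area = float(m1.sum())
    perimeter = float(measure.perimeter(m1, neighborhood=4))
    eq_diam = 2.0 * np.sqrt(area / np.pi)
    volume = float(stack.height[m1].sum())
    seed_height = float(np.median(stack.height[m2]))
    circularity = (area * 4.0) / (eq_diam * perimeter)
    plumpness = seed_height / eq_diam
    return {
        "seed_height": seed_height,
        "equivalent_diameter": float(eq_diam),
        "area": area,
        "plumpness": float(plumpness),
        "perimeter": perimeter,
        "volume": volume,
        "circularity": float(circularity),
    }


def extract_seed_features(stack: ImageStack, masks: MaskPair) -> SeedFeatures:
    """All 13 features for one seed."""
    factors = colour_factors(stack, masks.m2)
    ss = size_shape_features(stack, masks)
    return SeedFeatures(
        violet_factor=float(factors[0]),
        blue_factor=float(factors[1]),
        green_factor=float(factors[2]),
        orange_factor=float(factors[3]),
        red_factor=float(factors[4]),
        nir_factor=float(factors[5]),
        **ss,
    )


def sample_features(seed_features: Iterable[SeedFeatures]) -> np.ndarray:
    """Coordinate-wise median feature vector across a sample's seeds.

    Even counts use the midpoint of the two central order statistics.
    """
    mat = np.array([f.as_array() for f in seed_features], dtype=float)
    if mat.size == 0:
        raise ValueError("sample has no seeds")
    return np.median(mat, axis=0)


@dataclass(frozen=True)
class Standardiser:
    """Per-feature location/scale fitted on the calibration set."""

    mean: np.ndarray
    sd: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES


def fit_standardiser(calibration_records: Sequence[SampleRecord]) -> Standardiser:
    """Fit per-feature mean and standard deviation (ddof=1) on calibration records."""
    if len(calibration_records) < 2:
        raise ValueError("need at least 2 calibration records to standardise")
    mat = np.array([r.raw_features for r in calibration_records], dtype=float)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        bad = ", ".join(FEATURE_NAMES[i] for i in zero)
        raise ValueError(f"zero-variance feature(s) in calibration set: {bad}")
    return Standardiser(mean=mean, sd=sd)


def apply_standardiser(
    standardiser: Standardiser, records: Iterable[SampleRecord]
) -> list[SampleRecord]:
    """Populate ``std_features`` on each record (in place) and return them.

    Validation records are standardised with the calibration parameters,
    never their own statistics.
    """
    records = list(records)
    for r in records:
        r.std_features = (np.asarray(r.raw_features, float) - standardiser.mean) / standardiser.sd
    return records
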