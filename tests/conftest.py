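import numpy as np
import pytest

from peagrade import pipeline as pl
from peagrade import synth
from peagrade.features import FEATURE_NAMES, SampleRecord
from peagrade.synth import CellCount, DatasetDesign, GradeSpec, ImageStack

#: Reduced design used by unit tests: all 8 grades, 4 calibration + 2
#: validation samples each, 4 seeds per sample.
_SMALL_CELLS = {
    "White": (4, 1, 2, 0),
    "Blue": (4, 0, 2, 0),
    "Mottled Dun": (4, 2, 2, 1),
    "Kaspa Dun": (4, 2, 2, 1),
    "Green Dun": (4, 0, 2, 0),
    "Yellow Forage": (4, 4, 2, 2),
    "Marrowfat": (4, 0, 2, 0),
    "Kaspa type": (4, 2, 2, 1),
}


def small_cells() -> dict[tuple[str, str], CellCount]:
    cells = {}
    for grade, (ct, cd, vt, vd) in _SMALL_CELLS.items():
        cells[(grade, "calibration")] = CellCount(ct, cd)
        cells[(grade, "validation")] = CellCount(vt, vd)
    return cells


@pytest.fixture(scope="session")
def small_design() -> DatasetDesign:
    return DatasetDesign(cells=small_cells(), seeds_per_sample=4, rng_seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return synth.generate_dataset(small_design)


@pytest.fixture(scope="session")
def small_records(small_dataset):
    records = pl.extract_records(small_dataset)
    pl.standardise_records(records)
    return records


@pytest.fixture(scope="session")
def grade_specs():
    return synth.default_grade_specs()


@pytest.fixture()
def clean_stack(grade_specs) -> ImageStack:
    return synth.render_seed(grade_specs[0], rng_seed=7)


@pytest.fixture()
def smooth_spec() -> GradeSpec:
    """A deterministic, noise-free ellipse spec for geometric oracles."""
    return GradeSpec(
        "test", (1, 1, 1, 1, 1, 1), (20.0, 14.0), 0.0, 200.0, 0.0, shape_noise=0.0
    )


def make_stack(height: np.ndarray, factor: float = 2.0) -> ImageStack:
    """Stack with intensity = factor * height in every channel."""
    intensity = np.repeat(height[None] * factor, 6, axis=0)
    return ImageStack(intensity=intensity, height=height)


def make_record(
    values: dict[str, float],
    sample_id: str = "s",
    grade: str = "White",
    defective: bool = False,
    split: str = "calibration",
) -> SampleRecord:
    """Record whose raw and standardised features are equal; unspecified
    features are zero."""
    vec = np.zeros(len(FEATURE_NAMES))
    for name, v in values.items():
        vec[FEATURE_NAMES.index(name)] = v
    return SampleRecord(
        sample_id=sample_id,
        grade=grade,
        split=split,
        defective=defective,
        raw_features=vec,
        std_features=vec.copy(),
    )
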