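"""Synthetic seed image-stack generator.

Produces per-seed stacks of six colour-intensity images (violet, blue,
green, orange, red, NIR) plus a co-registered surface-height image, and
whole calibration/validation datasets with grade labels and defect flags.
The rendering model is deliberately simple: an elliptical height dome with
per-channel intensity proportional to surface height, so that the
height-corrected colour factors computed downstream recover the grade's
reflectance coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "CHANNELS",
    "GRADE_NAMES",
    "DEFECT_KINDS",
    "GradeSpec",
    "DefectProfile",
    "DatasetDesign",
    "CellCount",
    "ImageStack",
    "Sample",
    "Dataset",
    "default_grade_specs",
    "default_design",
    "render_seed",
    "generate_dataset",
]

#: Colour channel order used everywhere: short to long wavelength, then NIR.
CHANNELS = ("violet", "blue", "green", "orange", "red", "nir")

#: The eight market grades, in dataset-design order.
GRADE_NAMES = (
    "White",
    "Blue",
    "Mottled Dun",
    "Kaspa Dun",
    "Green Dun",
    "Yellow Forage",
    "Marrowfat",
    "Kaspa type",
)

DEFECT_KINDS = ("none", "disease_stain", "exposed_cotyledon", "shrivel", "insect")

# Reflectance of exposed cotyledon tissue: yellow interior, so depleted at
# short wavelengths and strong in the green-orange-red band.
_COTYLEDON_REFLECTANCE = np.array([0.18, 0.55, 1.25, 1.45, 1.20, 1.00])


class Speckle(NamedTuple):
    """Natural dark seed-coat speckling (Mottled Dun / Kaspa-type coats)."""

    density: float  # fraction of footprint covered by dots
    darkness: float  # multiplicative intensity factor inside dots (<1)


@dataclass(frozen=True)
class GradeSpec:
    """Rendering parameters for one market grade.

    Parameters
    ----------
    grade_name : str
        One of the eight market grades.
    reflectance : sequence of 6 floats
        Per-channel reflectance coefficients, order violet..NIR, all > 0.
        These are what the colour factors recover on clean seeds.
    semi_axes : (float, float)
        Mean seed semi-axes (row, column) in pixels.
    size_sd : float
        Between-seed standard deviation of each semi-axis, pixels.
    dome_height : float
        Mean peak height in height units.
    dome_sd : float
        Between-seed standard deviation of peak height.
    shape_noise : float
        Amplitude of low-frequency boundary irregularity, pixels.
    speckle : Speckle or None
        Optional natural coat speckling.
    """

    grade_name: str
    reflectance: tuple[float, ...]
    semi_axes: tuple[float, float]
    size_sd: float
    dome_height: float
    dome_sd: float
    shape_noise: float = 0.8
    speckle: Speckle | None = None

    def __post_init__(self) -> None:
        refl = np.asarray(self.reflectance, dtype=float)
        if refl.shape != (6,) or not np.all(refl > 0):
            raise ValueError("reflectance must be 6 strictly positive values")
        if self.size_sd < 0 or self.size_sd >= min(self.semi_axes):
            raise ValueError("size_sd must be nonnegative and smaller than the mean semi-axes")
        if self.dome_sd < 0 or self.dome_sd >= self.dome_height:
            raise ValueError("dome_sd must be nonnegative and smaller than dome_height")
        object.__setattr__(self, "reflectance", tuple(float(r) for r in refl))

    @property
    def reflectance_array(self) -> np.ndarray:
        return np.asarray(self.reflectance, dtype=float)


@dataclass(frozen=True)
class DefectProfile:
    """A seed-level defect: kind plus a severity in [0, 1].

    ``patch_density`` and ``patch_radius`` tune the defect patch model;
    sensible defaults are derived from severity when left at ``None``.
    """

    kind: str = "none"
    severity: float = 0.0
    patch_density: float | None = None
    patch_radius: tuple[float, float] = (2.0, 6.0)

    def __post_init__(self) -> None:
        if self.kind not in DEFECT_KINDS:
            raise ValueError(f"unknown defect kind {self.kind!r}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.kind == "none" and self.severity != 0.0:
            raise ValueError("kind='none' requires severity 0")


NO_DEFECT = DefectProfile()


class CellCount(NamedTuple):
    total: int
    defective: int


@dataclass(frozen=True)
class DatasetDesign:
    """Sampling design: per (grade, split) totals and defective counts."""

    cells: dict[tuple[str, str], CellCount]
    seeds_per_sample: int = 30
    rng_seed: int = 0
    image_shape: tuple[int, int] = (96, 96)
    noise_sd: float = 0.05
    reflect_jitter: float = 0.04
    defective_seed_fraction: float = 0.85
    severity_range: tuple[float, float] = (0.40, 0.70)
    defect_kinds: tuple[str, ...] = ("disease_stain", "exposed_cotyledon", "shrivel", "insect")

    def __post_init__(self) -> None:
        if self.seeds_per_sample < 1:
            raise ValueError("seeds_per_sample must be >= 1")
        if not 0.75 <= self.defective_seed_fraction <= 1.0:
            raise ValueError("defective_seed_fraction must be in [0.75, 1]")
        for (grade, split), cell in self.cells.items():
            if split not in ("calibration", "validation"):
                raise ValueError(f"unknown split {split!r}")
            if cell.defective > cell.total or cell.defective < 0 or cell.total < 0:
                raise ValueError(
                    f"cell ({grade}, {split}): defective count {cell.defective} "
                    f"exceeds total {cell.total}"
                )
        for kind in self.defect_kinds:
            if kind not in DEFECT_KINDS or kind == "none":
                raise ValueError(f"invalid defect kind {kind!r}")

    def split_counts(self, split: str) -> CellCount:
        total = sum(c.total for (_, s), c in self.cells.items() if s == split)
        defective = sum(c.defective for (_, s), c in self.cells.items() if s == split)
        return CellCount(total, defective)


@dataclass(frozen=True)
class ImageStack:
    """One seed's six colour-intensity images plus its height image.

    ``intensity`` has shape (6, H, W) in channel order violet..NIR;
    ``height`` has shape (H, W). Background height is exactly zero.
    """

    intensity: np.ndarray
    height: np.ndarray

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        hgt = np.asarray(self.height, dtype=float)
        if inten.ndim != 3 or inten.shape[0] != 6:
            raise ValueError("intensity must have shape (6, H, W)")
        if hgt.shape != inten.shape[1:]:
            raise ValueError("height shape must match intensity image shape")
        if not (np.all(np.isfinite(inten)) and np.all(np.isfinite(hgt))):
            raise ValueError("all pixel values must be finite")
        if inten.min() < 0 or hgt.min() < 0:
            raise ValueError("all pixel values must be >= 0")
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "height", hgt)

    @property
    def shape(self) -> tuple[int, int]:
        return self.height.shape

    def channel(self, name: str) -> np.ndarray:
        return self.intensity[CHANNELS.index(name)]


@dataclass
class Sample:
    sample_id: str
    grade: str
    split: str
    defective: bool
    stacks: list[ImageStack]
    defects: list[DefectProfile]


@dataclass
class Dataset:
    design: DatasetDesign
    samples: list[Sample]

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, split: str | None = None, defective: bool | None = None) -> list[Sample]:
        out = self.samples
        if split is not None:
            out = [s for s in out if s.split == split]
        if defective is not None:
            out = [s for s in out if s.defective == defective]
        return out


def default_grade_specs() -> list[GradeSpec]:
    """The eight default market-grade rendering specs.

    Reflectance vectors are pairwise distinct and chosen so that grade
    means separate on the blue/green/orange/red channels while the NIR
    channel is nearly flat across grades. Marrowfat is rendered much
    larger than the other grades and Yellow Forage much smaller.
    """
    s = Speckle(density=0.08, darkness=0.45)
    return [
        GradeSpec("White", (0.55, 0.95, 1.10, 1.18, 1.20, 1.00), (26.0, 24.0), 1.5, 220.0, 15.0),
        GradeSpec("Blue", (0.70, 1.12, 0.95, 0.80, 0.85, 1.00), (25.0, 23.0), 1.5, 210.0, 15.0),
        GradeSpec("Mottled Dun", (0.45, 0.70, 0.76, 0.86, 0.90, 1.02), (24.0, 22.0), 1.5, 200.0, 15.0, speckle=s),
        GradeSpec("Kaspa Dun", (0.50, 0.80, 0.86, 1.00, 0.95, 0.98), (24.0, 21.0), 1.5, 205.0, 15.0),
        GradeSpec("Green Dun", (0.40, 0.76, 1.00, 0.90, 0.80, 1.00), (25.0, 22.0), 1.5, 210.0, 15.0),
        GradeSpec("Yellow Forage", (0.60, 0.86, 1.05, 1.30, 1.10, 1.01), (18.0, 15.0), 1.2, 160.0, 12.0),
        GradeSpec("Marrowfat", (0.50, 0.90, 1.20, 1.06, 1.00, 0.99), (34.0, 28.0), 1.8, 260.0, 18.0, shape_noise=1.5),
        GradeSpec("Kaspa type", (0.65, 1.00, 0.90, 1.10, 1.05, 1.00), (23.0, 21.0), 1.5, 200.0, 15.0, speckle=s),
    ]


#: Table-style default design: per grade, (calibration total, calibration
#: defective, validation total, validation defective).
_DEFAULT_CELLS = {
    "White": (50, 4, 45, 4),
    "Blue": (31, 0, 44, 0),
    "Mottled Dun": (7, 4, 5, 4),
    "Kaspa Dun": (13, 7, 8, 6),
    "Green Dun": (16, 0, 5, 1),
    "Yellow Forage": (5, 5, 6, 6),
    "Marrowfat": (6, 0, 2, 0),
    "Kaspa type": (47, 19, 27, 18),
}


def default_design(rng_seed: int = 0, **overrides) -> DatasetDesign:
    """The default dataset design: 175 calibration samples (39 defective)
    and 142 validation samples (39 defective), split per grade."""
    cells: dict[tuple[str, str], CellCount] = {}
    for grade, (ct, cd, vt, vd) in _DEFAULT_CELLS.items():
        cells[(grade, "calibration")] = CellCount(ct, cd)
        cells[(grade, "validation")] = CellCount(vt, vd)
    return DatasetDesign(cells=cells, rng_seed=rng_seed, **overrides)


def _fourier_boundary_noise(rng: np.random.Generator, theta: np.ndarray, amplitude: float) -> np.ndarray:
    """Low-frequency radial perturbation g(theta), mean ~1, in relative units."""
    g = np.ones_like(theta)
    for k in (2, 3, 4):
        g += (amplitude / k) * rng.normal() * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return g


def _disk_patches(
    rng: np.random.Generator,
    support: np.ndarray,
    target_fraction: float,
    radius_range: tuple[float, float],
) -> np.ndarray:
    """Union of random disks over the support until the target coverage
    fraction of support pixels is reached (uniform seeded placement)."""
    patch = np.zeros(support.shape, dtype=bool)
    ys, xs = np.nonzero(support)
    if len(ys) == 0 or target_fraction <= 0:
        return patch
    n_support = len(ys)
    yy, xx = np.indices(support.shape)
    for _ in range(300):
        if patch.sum() >= target_fraction * n_support:
            break
        i = int(rng.integers(n_support))
        r = rng.uniform(*radius_range)
        patch |= (yy - ys[i]) ** 2 + (xx - xs[i]) ** 2 <= r * r
    return patch & support


def render_seed(
    spec: GradeSpec,
    defect: DefectProfile = NO_DEFECT,
    rng_seed: int | np.random.SeedSequence = 0,
    *,
    shape: tuple[int, int] = (96, 96),
    noise_sd: float = 0.05,
    reflect_jitter: float = 0.04,
) -> ImageStack:
    """Render one seed as an ImageStack.

    The seed is an elliptical paraboloid height dome (zero outside its
    footprint) with low-frequency boundary irregularity. Intensity in
    channel c is ``reflectance[c] * height * lognormal noise``, so the
    height-corrected colour factor recovers ``reflectance[c]``. Defects
    modify the reflectance map (disease stain, exposed cotyledon) or the
    height field (shrivel, insect). Deterministic for a fixed ``rng_seed``.
    """
    nrow, ncol = shape
    if nrow <= 0 or ncol <= 0:
        raise ValueError("image dimensions must be positive")
    ss = rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    geom_ss, defect_ss, noise_ss = ss.spawn(3)
    rng_geom = np.random.default_rng(geom_ss)
    rng_defect = np.random.default_rng(defect_ss)
    rng_noise = np.random.default_rng(noise_ss)

    # --- geometry -----------------------------------------------------
    a = max(3.0, rng_geom.normal(spec.semi_axes[0], spec.size_sd))
    b = max(3.0, rng_geom.normal(spec.semi_axes[1], spec.size_sd))
    # keep the footprint inside the frame
    a = min(a, nrow / 2 - 2)
    b = min(b, ncol / 2 - 2)
    peak = max(50.0, rng_geom.normal(spec.dome_height, spec.dome_sd))

    cy, cx = (nrow - 1) / 2.0, (ncol - 1) / 2.0
    yy, xx = np.indices(shape, dtype=float)
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    g = _fourier_boundary_noise(rng_geom, theta, spec.shape_noise / min(a, b))
    g = np.clip(g, 0.6, 1.4)
    u = (dy / (a * g)) ** 2 + (dx / (b * g)) ** 2
    height = peak * np.clip(1.0 - u, 0.0, None)
    footprint = height > 0

    # per-channel reflectance map; start uniform with per-seed jitter
    refl = spec.reflectance_array * rng_geom.lognormal(0.0, reflect_jitter, size=6)
    refl_map = refl[:, None, None] * np.ones((6,) + shape)

    if spec.speckle is not None:
        dots = _disk_patches(rng_geom, footprint, spec.speckle.density, (1.0, 2.5))
        refl_map[:, dots] *= spec.speckle.darkness

    # --- defects ------------------------------------------------------
    sev = defect.severity
    if defect.kind == "disease_stain" and sev > 0:
        frac = defect.patch_density if defect.patch_density is not None else 0.30 + 0.50 * sev
        patches = _disk_patches(rng_defect, footprint, frac, defect.patch_radius)
        refl_map[:, patches] *= 1.0 - 0.85 * sev
    elif defect.kind == "exposed_cotyledon" and sev > 0:
        frac = defect.patch_density if defect.patch_density is not None else 0.30 + 0.50 * sev
        patches = _disk_patches(rng_defect, footprint, frac, defect.patch_radius)
        refl_map[:, patches] = _COTYLEDON_REFLECTANCE[:, None]
    elif defect.kind == "shrivel" and sev > 0:
        height = height * (1.0 - sev)
        # dimples are carved only into the low flank of the dome (below the
        # 40th height percentile) so the median height scales exactly with
        # (1 - severity)
        pos = height[footprint]
        q40 = np.quantile(pos, 0.40)
        low_band = footprint & (height < q40)
        dimples = _disk_patches(rng_defect, low_band, 0.5, (1.5, 4.0))
        height = np.where(dimples, height * (1.0 - 0.5 * sev), height)
    elif defect.kind == "insect" and sev > 0:
        frac = defect.patch_density if defect.patch_density is not None else 0.20 + 0.45 * sev
        holes = _disk_patches(rng_defect, footprint, frac, (1.5, 3.5))
        refl_map[:, holes] = _COTYLEDON_REFLECTANCE[:, None]
        height = np.where(holes, height * 0.45, height)

    # --- intensity ----------------------------------------------------
    noise = rng_noise.lognormal(0.0, noise_sd, size=(6,) + shape)
    intensity = refl_map * height[None, :, :] * noise
    intensity[:, ~footprint] = 0.0
    return ImageStack(intensity=intensity, height=height)


def _seed_defects(
    rng: np.random.Generator, design: DatasetDesign, n_seeds: int, defective: bool
) -> list[DefectProfile]:
    """Per-seed defect profiles for one sample.

    Defective samples carry a single defect kind with >= 75% of seeds
    affected; non-defective samples carry no defective seeds (< 5%).
    """
    if not defective:
        return [NO_DEFECT] * n_seeds
    kind = str(rng.choice(design.defect_kinds))
    n_def = max(math.ceil(0.75 * n_seeds), round(design.defective_seed_fraction * n_seeds))
    n_def = min(n_def, n_seeds)
    flags = np.zeros(n_seeds, dtype=bool)
    flags[rng.permutation(n_seeds)[:n_def]] = True
    lo, hi = design.severity_range
    return [
        DefectProfile(kind, float(rng.uniform(lo, hi))) if f else NO_DEFECT
        for f in flags
    ]


def generate_dataset(
    design: DatasetDesign | None = None,
    specs: Sequence[GradeSpec] | None = None,
) -> Dataset:
    """Generate a full labelled dataset from a design.

    Cell counts match the design exactly; the whole dataset is a pure
    function of ``design.rng_seed`` (per-sample and per-seed sub-streams
    are spawned deterministically).
    """
    if design is None:
        design = default_design()
    if specs is None:
        specs = default_grade_specs()
    spec_by_name = {s.grade_name: s for s in specs}
    for (grade, _split) in design.cells:
        if grade not in spec_by_name:
            raise ValueError(f"no GradeSpec for grade {grade!r}")

    root = np.random.SeedSequence(design.rng_seed)
    n_samples = sum(c.total for c in design.cells.values())
    sample_seeds = root.spawn(n_samples)

    samples: list[Sample] = []
    idx = 0
    for (grade, split), cell in design.cells.items():
        spec = spec_by_name[grade]
        for j in range(cell.total):
            defective = j < cell.defective
            sub = sample_seeds[idx].spawn(design.seeds_per_sample + 1)
            idx += 1
            rng_sample = np.random.default_rng(sub[0])
            defects = _seed_defects(rng_sample, design, design.seeds_per_sample, defective)
            stacks = [
                render_seed(
                    spec,
                    defects[k],
                    sub[k + 1],
                    shape=design.image_shape,
                    noise_sd=design.noise_sd,
                    reflect_jitter=design.reflect_jitter,
                )
                for k in range(design.seeds_per_sample)
            ]
            tag = "def" if defective else "ok"
            sample_id = f"{split[:3]}-{grade.replace(' ', '_')}-{j:03d}-{tag}"
            samples.append(Sample(sample_id, grade, split, defective, stacks, defects))
    return Dataset(design=design, samples=samples)
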