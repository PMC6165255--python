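"""Seeded synthetic histology-like texture images.

Real H&E tiles of neuroblastic tumours differ between subtypes mainly in
the size distribution and packing density of cell nuclei, with strong
*within*-class variation in cell size — the property that motivates
scale-invariant features.  The generator emulates exactly that: each
class is a texture of elliptical Gaussian "cells" whose radius
distribution, density, eccentricity and contrast are class parameters,
with a per-image global scale jitter drawn from a configurable range.

The output is grayscale (the feature pipeline converts RGB to gray
anyway); an optional H&E-like colorization exists solely to exercise the
RGB path.  Everything is deterministic per (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

IMAGE_SIZE = 300  # pixels per side of every generated tile
BACKGROUND = 0.85  # light eosin-like background intensity
IMAGES_PER_PATIENT = 5
IMAGES_PER_SECTION = 10

__all__ = [
    "ClassSpec",
    "SyntheticDataset",
    "default_class_specs",
    "render_image",
    "generate_dataset",
    "colorize_hne",
]


@dataclass(frozen=True)
class ClassSpec:
    """Texture parameters of one synthetic tissue class.

    ``cell_density`` is in cells per 10^4 px^2 (a 300x300 tile covers
    9 such units).  ``scale_jitter`` is the range of a per-image global
    multiplier on all cell radii, emulating within-class variation in
    cell size; ``(1.0, 1.0)`` disables it.
    """

    name: str
    cell_radius_mean: float
    cell_radius_sd: float
    cell_density: float
    cell_eccentricity: float = 0.3
    contrast: float = 0.55
    noise_sd: float = 0.02
    scale_jitter: tuple[float, float] = (0.7, 1.4)

    def __post_init__(self) -> None:
        if not self.cell_radius_mean > 1:
            raise ValueError("cell_radius_mean must exceed 1 px")
        if not self.cell_density > 0:
            raise ValueError("cell_density must be positive")
        if not 0 <= self.cell_eccentricity < 1:
            raise ValueError("cell_eccentricity must be in [0, 1)")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must be in (0, 1]")
        for v in (
            self.cell_radius_sd,
            self.noise_sd,
            *self.scale_jitter,
        ):
            if not np.isfinite(v) or v < 0:
                raise ValueError("all parameters must be finite and >= 0")


def default_class_specs() -> list[ClassSpec]:
    """The five default texture classes.

    Sizes and densities bracket the small-round-blue-cell appearance of
    undifferentiated tumours (many small nuclei) against the sparse large
    ganglion cells of ganglioneuroma, with a mixed-size class in between.
    """
    return [
        ClassSpec("small-dense", 3.0, 0.6, 10.0, cell_eccentricity=0.2),
        ClassSpec("small-sparse", 3.0, 0.6, 3.0, cell_eccentricity=0.2),
        ClassSpec("large-dense", 8.0, 1.6, 6.0, cell_eccentricity=0.5),
        ClassSpec("large-sparse", 8.0, 1.6, 2.0, cell_eccentricity=0.5),
        ClassSpec("mixed-size", 5.0, 2.5, 5.0, cell_eccentricity=0.35),
    ]


@dataclass
class SyntheticDataset:
    """A balanced labeled image set with pseudo-patient/section structure."""

    images: list[np.ndarray]
    labels: list[str]
    patient_ids: list[str]
    section_ids: list[str]
    seed: int
    specs: list[ClassSpec]

    def __len__(self) -> int:
        return len(self.images)


def _expected_coverage(spec: ClassSpec) -> float:
    area = IMAGE_SIZE * IMAGE_SIZE
    n = spec.cell_density * area / 1e4
    mean_jitter = 0.5 * (spec.scale_jitter[0] + spec.scale_jitter[1])
    r = spec.cell_radius_mean * mean_jitter
    return n * np.pi * r * r / area


def render_image(spec: ClassSpec, seed: int) -> np.ndarray:
    """Render one 300x300 tile of the given class.

    Cells are placed uniformly at Poisson-distributed count
    (mean = density x 9 for the 300x300 tile); each is an elliptical
    Gaussian dip below the light background, with per-cell radius drawn
    from N(mean, sd) and the whole image sharing one scale-jitter draw.
    """
    if _expected_coverage(spec) > 0.5:
        raise ValueError(
            f"degenerate texture: class {spec.name!r} implies "
            f"{100 * _expected_coverage(spec):.0f}% expected blob coverage (> 50%)"
        )
    rng = np.random.default_rng(seed)
    img = np.full((IMAGE_SIZE, IMAGE_SIZE), BACKGROUND)
    n_cells = rng.poisson(spec.cell_density * IMAGE_SIZE * IMAGE_SIZE / 1e4)
    jitter = rng.uniform(*spec.scale_jitter)
    for _ in range(n_cells):
        cy, cx = rng.uniform(0, IMAGE_SIZE, size=2)
        r = max(rng.normal(spec.cell_radius_mean, spec.cell_radius_sd), 1.5)
        r *= jitter
        ecc = spec.cell_eccentricity
        a, b = r, r * np.sqrt(1.0 - ecc * ecc)
        phi = rng.uniform(0, np.pi)
        amp = spec.contrast * rng.uniform(0.8, 1.0)
        # local bounding box: +-3a covers the Gaussian support
        ext = int(np.ceil(3 * a)) + 1
        rlo, rhi = max(int(cy) - ext, 0), min(int(cy) + ext + 1, IMAGE_SIZE)
        clo, chi = max(int(cx) - ext, 0), min(int(cx) + ext + 1, IMAGE_SIZE)
        if rlo >= rhi or clo >= chi:
            continue
        yy, xx = np.mgrid[rlo:rhi, clo:chi]
        dx, dy = xx - cx, yy - cy
        u = np.cos(phi) * dx + np.sin(phi) * dy
        v = -np.sin(phi) * dx + np.cos(phi) * dy
        # Gaussian profile with half-amplitude radius ~ r
        q = (u / a) ** 2 + (v / b) ** 2
        img[rlo:rhi, clo:chi] -= amp * np.exp(-1.386 * q / 2.0)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(
    specs: list[ClassSpec],
    images_per_class: int,
    seed: int,
) -> SyntheticDataset:
    """Generate a balanced dataset with pseudo-patients and pseudo-sections.

    Per-image seeds are derived from the master seed so regeneration is
    bit-identical.  Images are grouped into pseudo-patients of
    ``IMAGES_PER_PATIENT`` consecutive same-class images and
    pseudo-sections of ``IMAGES_PER_SECTION``, exercising patient-level
    recognition rate and section-level majority voting.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 class specs")
    if images_per_class < 2:
        raise ValueError("need at least 2 images per class")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate class names in {names}")

    root = np.random.SeedSequence(seed)
    per_class = root.spawn(len(specs))
    images: list[np.ndarray] = []
    labels: list[str] = []
    patient_ids: list[str] = []
    section_ids: list[str] = []
    for ci, (spec, seq) in enumerate(zip(specs, per_class)):
        child_seeds = seq.generate_state(images_per_class) % (2**31)
        for j in range(images_per_class):
            images.append(render_image(spec, int(child_seeds[j])))
            labels.append(spec.name)
            patient_ids.append(f"P{ci:02d}_{j // IMAGES_PER_PATIENT:03d}")
            section_ids.append(f"S{ci:02d}_{j // IMAGES_PER_SECTION:03d}")
    return SyntheticDataset(images, labels, patient_ids, section_ids, seed, list(specs))


def colorize_hne(gray: np.ndarray) -> np.ndarray:
    """Map a grayscale tile to H&E-like purple/pink RGB (uint8).

    Dark cells become hematoxylin purple, light background eosin pink.
    Exists to exercise the RGB-to-grayscale input path, not for realism.
    """
    g = np.clip(np.asarray(gray, dtype=float), 0, 1)[..., None]
    nucleus = np.array([0.45, 0.25, 0.60])  # purple
    background = np.array([0.95, 0.80, 0.88])  # pink
    rgb = nucleus + (background - nucleus) * g
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)
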