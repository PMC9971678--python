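"""Synthetic CT phantoms with known muscle composition.

A phantom is a single axial "neck" slice: a soft-tissue disc on an air
background, a high-attenuation vertebral body in the middle, and two
elliptical paraspinal compartments flanking it.  Inside each compartment
every pixel is assigned to the fatty or lean class by a seeded draw that
hits the requested fat fraction *exactly in pixel count* (largest-
remainder rounding), then HU values are sampled from per-class normal
distributions.  Optional Gaussian noise and blur are applied afterwards,
so the pre-noise class counts are exact ground truth for validating the
threshold-based composition scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, stats

from .composition import CompartmentROI, CTSlice

__all__ = ["PhantomSpec", "GroundTruth", "generate_phantom"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic neck slice.

    HU means default to lean muscle at 50 HU and fatty muscle at 0 HU,
    strictly inside the lean [30, 100] and fatty [-30, 29] bands so that
    with ``noise_sd_hu=0`` every planted pixel classifies correctly.
    ``target_fat_fraction`` applies to both compartments; pass a pair to
    set them separately.
    """

    grid_size: tuple[int, int] = (128, 128)
    pixel_spacing_mm: tuple[float, float] = (0.7, 0.7)
    target_fat_fraction: float | tuple[float, float] = 0.3
    lean_hu_mean: float = 50.0
    lean_hu_sd: float = 8.0
    fatty_hu_mean: float = 0.0
    fatty_hu_sd: float = 10.0
    background_hu: float = -1000.0
    soft_tissue_hu: float = 60.0
    bone_hu: float = 700.0
    noise_sd_hu: float = 0.0
    blur_fwhm_mm: float = 0.0
    # compartment geometry in fractions of the grid; (row_center, col_center,
    # row_semiaxis, col_semiaxis) for the left ellipse, mirrored on the right
    compartment_geometry: tuple[float, float, float, float] = (0.55, 0.30, 0.22, 0.13)
    seed: int = 0

    def __post_init__(self):
        ff = self.target_fat_fraction
        fractions = (ff, ff) if np.isscalar(ff) else tuple(ff)
        if len(fractions) != 2 or not all(0.0 <= f <= 1.0 for f in fractions):
            raise ValueError("target_fat_fraction must lie in [0, 1]")
        object.__setattr__(self, "target_fat_fraction", fractions)
        if not all(s > 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be > 0")
        if self.noise_sd_hu < 0 or self.blur_fwhm_mm < 0:
            raise ValueError("noise_sd_hu and blur_fwhm_mm must be >= 0")
        if not (30.0 <= self.lean_hu_mean <= 100.0):
            raise ValueError("lean_hu_mean must lie in the lean band [30, 100] HU")
        if not (-30.0 <= self.fatty_hu_mean <= 29.0):
            raise ValueError("fatty_hu_mean must lie in the fatty band [-30, 29] HU")


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-compartment class counts and the implied true FFMF."""

    lean_pixels: dict = field(default_factory=dict)   # side -> count
    fatty_pixels: dict = field(default_factory=dict)  # side -> count
    fat_fraction: dict = field(default_factory=dict)  # side -> planted fraction

    def ffmf_percent(self, side: str = "combined") -> float:
        """True FFMF = 100 * lean / (lean + fatty), from planted counts."""
        if side == "combined":
            lean = sum(self.lean_pixels.values())
            fatty = sum(self.fatty_pixels.values())
        else:
            lean = self.lean_pixels[side]
            fatty = self.fatty_pixels[side]
        total = lean + fatty
        if total == 0:
            raise ValueError("empty compartment: FFMF undefined")
        return 100.0 * lean / total

    def to_dict(self) -> dict:
        return {
            "lean_pixels": dict(self.lean_pixels),
            "fatty_pixels": dict(self.fatty_pixels),
            "fat_fraction": dict(self.fat_fraction),
            "ffmf_percent": {
                s: self.ffmf_percent(s) for s in ("left", "right", "combined")
            },
        }


def _ellipse_mask(shape, center_rc, semi_rc) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = center_rc
    ra, ca = semi_rc
    return ((rr - r0) / ra) ** 2 + ((cc - c0) / ca) ** 2 <= 1.0


def _class_hu(mean: float, sd: float, band: tuple[float, float], n: int, rng) -> np.ndarray:
    """Per-class HU draws, truncated so the *stored* (rounded) value stays
    inside the class band.  Truncation keeps the planted class labels exact
    ground truth in the absence of added noise and blur; ``noise_sd_hu``
    is the knob that lets pixels leak across the thresholds."""
    lo, hi = band[0] - 0.499, band[1] + 0.499
    if sd == 0:
        return np.full(n, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _plant_classes(n_pixels: int, fat_fraction: float, rng) -> np.ndarray:
    """Boolean fatty-flags with the fat count fixed by largest-remainder
    rounding (round-half-up), positions shuffled by the seeded RNG."""
    n_fatty = int(np.floor(n_pixels * fat_fraction + 0.5))
    flags = np.zeros(n_pixels, dtype=bool)
    flags[:n_fatty] = True
    rng.shuffle(flags)
    return flags


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[CTSlice, CompartmentROI, CompartmentROI, GroundTruth]:
    """Build a phantom slice, its two compartment ROIs, and ground truth.

    Returns ``(ct, left_roi, right_roi, truth)``.  The stored HU grid is
    integer (rounded), mirroring how CT values are stored clinically; the
    composition scoring operates on those stored values.

    Raises
    ------
    ValueError : if the two compartments would overlap or touch the grid
        border (geometry too large for the grid).
    """
    rows, cols = spec.grid_size
    rng = np.random.default_rng(spec.seed)

    g = spec.compartment_geometry
    center_l = (g[0] * rows, g[1] * cols)
    center_r = (g[0] * rows, (1.0 - g[1]) * cols)
    semi = (g[2] * rows / 2.0, g[3] * cols / 2.0)
    left_mask = _ellipse_mask((rows, cols), center_l, semi)
    right_mask = _ellipse_mask((rows, cols), center_r, semi)
    if np.any(left_mask & right_mask):
        raise ValueError("compartment geometry makes the two compartments overlap")
    for name, m in (("left", left_mask), ("right", right_mask)):
        if m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any():
            raise ValueError(f"{name} compartment exceeds the grid")
        if not m.any():
            raise ValueError(f"{name} compartment is empty for this grid size")

    # neck disc and vertebral body
    neck = _ellipse_mask((rows, cols), (rows / 2.0, cols / 2.0), (rows * 0.45, cols * 0.45))
    vertebra = _ellipse_mask((rows, cols), (rows * 0.5, cols * 0.5), (rows * 0.10, cols * 0.08))
    img = np.full((rows, cols), spec.background_hu, dtype=float)
    img[neck] = spec.soft_tissue_hu
    img[vertebra] = spec.bone_hu

    truth = GroundTruth()
    for side, mask, frac in (
        ("left", left_mask, spec.target_fat_fraction[0]),
        ("right", right_mask, spec.target_fat_fraction[1]),
    ):
        n = int(mask.sum())
        fatty_flags = _plant_classes(n, frac, rng)
        hu = np.empty(n)
        hu[fatty_flags] = _class_hu(
            spec.fatty_hu_mean, spec.fatty_hu_sd, (-30.0, 29.0), int(fatty_flags.sum()), rng
        )
        hu[~fatty_flags] = _class_hu(
            spec.lean_hu_mean, spec.lean_hu_sd, (30.0, 100.0), int((~fatty_flags).sum()), rng
        )
        img[mask] = hu
        n_fatty = int(fatty_flags.sum())
        truth.fatty_pixels[side] = n_fatty
        truth.lean_pixels[side] = n - n_fatty
        truth.fat_fraction[side] = frac

    if spec.blur_fwhm_mm > 0:
        sigma_px = tuple(
            spec.blur_fwhm_mm * _FWHM_TO_SIGMA / s for s in spec.pixel_spacing_mm
        )
        img = ndimage.gaussian_filter(img, sigma=sigma_px)
    if spec.noise_sd_hu > 0:
        img = img + rng.normal(0.0, spec.noise_sd_hu, size=img.shape)

    stored = np.rint(img).astype(np.int16)
    ct = CTSlice(stored, spec.pixel_spacing_mm, meta={"phantom_seed": spec.seed})
    return (
        ct,
        CompartmentROI("left", mask=left_mask),
        CompartmentROI("right", mask=right_mask),
        truth,
    )
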