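"""HU-threshold muscle composition scoring for a single axial CT slice.

The scoring procedure classifies every pixel inside a traced paraspinal
compartment by its Hounsfield-unit value: fatty muscle in [-30, 29] HU,
lean muscle in [30, 100] HU, anything else (vessels, bone flecks, air)
stays in the compartment but is excluded from the muscle area.  The
fat-free muscle fraction (FFMF) is the lean muscle area divided by the
total muscle area (lean + fatty), expressed as a percentage.  Mean muscle
attenuation averages HU over the muscle pixels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import shapely

__all__ = [
    "CTSlice",
    "CompartmentROI",
    "Thresholds",
    "CompositionResult",
    "rasterize_roi",
    "classify_pixels",
    "compute_composition",
    "compose_slice",
]


@dataclass(frozen=True)
class CTSlice:
    """A 2D grid of Hounsfield units with physical pixel spacing.

    Parameters
    ----------
    hu : 2D array of HU values (int or float), finite.
    pixel_spacing_mm : (row_spacing, col_spacing) in millimetres, > 0.
    meta : optional free-form metadata passed through untouched.
    """

    hu: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        hu = np.asarray(self.hu)
        if hu.ndim != 2 or hu.size == 0:
            raise ValueError("hu grid must be a non-empty 2D array")
        if not np.all(np.isfinite(hu)):
            raise ValueError("hu grid contains non-finite values")
        rs, cs = self.pixel_spacing_mm
        if not (rs > 0 and cs > 0):
            raise ValueError(f"pixel spacing must be > 0, got {self.pixel_spacing_mm}")
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "pixel_spacing_mm", (float(rs), float(cs)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.hu.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1]


Side = Literal["left", "right", "combined"]


@dataclass
class CompartmentROI:
    """A paraspinal compartment, as a binary mask or a closed polygon.

    Exactly one of ``mask`` (bool array congruent with the slice) or
    ``polygon`` (vertices in pixel coordinates, rows/cols referring to
    pixel centers, >= 3 vertices, simple) must be given.
    """

    side: Side
    mask: Optional[np.ndarray] = None
    polygon: Optional[np.ndarray] = None

    def __post_init__(self):
        if (self.mask is None) == (self.polygon is None):
            raise ValueError("give exactly one of mask or polygon")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.ndim != 2:
                raise ValueError("mask must be 2D")
        else:
            poly = np.asarray(self.polygon, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError("polygon needs >= 3 (row, col) vertices")
            self.polygon = poly

    def to_mask(self, ct: CTSlice) -> np.ndarray:
        """Binary mask on the slice grid (rasterizing the polygon if needed)."""
        if self.mask is not None:
            if self.mask.shape != ct.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != slice shape {ct.shape}"
                )
            return self.mask
        return rasterize_roi(self.polygon, ct.shape)


def _find_self_intersection(poly: np.ndarray) -> Optional[tuple[int, int]]:
    """Return indices (i, j) of two properly crossing edges, or None.

    Adjacent edges sharing a vertex are allowed; a genuine crossing or
    overlap between non-adjacent edges makes the polygon non-simple.
    """
    n = len(poly)
    segs = [
        shapely.LineString([poly[i][::-1], poly[(i + 1) % n][::-1]]) for i in range(n)
    ]
    for i in range(n):
        for j in range(i + 1, n):
            adjacent = (j == i + 1) or (i == 0 and j == n - 1)
            if adjacent:
                continue
            if segs[i].intersects(segs[j]):
                return (i, j)
    return None


def rasterize_roi(polygon: np.ndarray | CompartmentROI, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon to a binary mask on a pixel grid.

    A pixel belongs to the mask iff its center (integer row/col coordinate)
    lies inside the polygon under the even-odd rule; a center exactly on
    the boundary counts as inside.

    Parameters
    ----------
    polygon : (n, 2) array of (row, col) vertices, or a polygon ROI.
    shape : (rows, cols) of the target grid.

    Raises
    ------
    ValueError : if the polygon self-intersects (the offending edge pair
        is named in the message).
    """
    if isinstance(polygon, CompartmentROI):
        if polygon.polygon is None:
            raise ValueError("ROI holds a mask, nothing to rasterize")
        polygon = polygon.polygon
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("polygon needs >= 3 (row, col) vertices")

    # shapely speaks (x, y); we map col -> x, row -> y
    shp = shapely.Polygon(poly[:, ::-1])
    if not shp.is_valid:
        pair = _find_self_intersection(poly)
        if pair is not None:
            raise ValueError(
                f"polygon self-intersects: edge {pair[0]} (vertices {pair[0]}->"
                f"{(pair[0] + 1) % len(poly)}) crosses edge {pair[1]} (vertices "
                f"{pair[1]}->{(pair[1] + 1) % len(poly)})"
            )
        raise ValueError("polygon is not a valid simple ring")

    rows, cols = shape
    # restrict the candidate pixels to the polygon's bounding box
    rmin = max(0, int(np.floor(poly[:, 0].min())))
    rmax = min(rows - 1, int(np.ceil(poly[:, 0].max())))
    cmin = max(0, int(np.floor(poly[:, 1].min())))
    cmax = min(cols - 1, int(np.ceil(poly[:, 1].max())))
    mask = np.zeros(shape, dtype=bool)
    if rmin > rmax or cmin > cmax:
        return mask
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij"
    )
    pts = shapely.points(cc.ravel().astype(float), rr.ravel().astype(float))
    inside = shapely.covers(shp, pts)  # boundary counts as inside
    mask[rr.ravel()[inside], cc.ravel()[inside]] = True
    return mask


@dataclass(frozen=True)
class Thresholds:
    """Inclusive HU bands separating fatty from lean muscle.

    Defaults follow the densitometric convention of fatty muscle in
    [-30, 29] HU and lean muscle in [30, 100] HU on integer-stored CT
    values.  For float-valued grids the fatty band is effectively
    [-30, 30) so the two bands stay contiguous.
    """

    fatty_low: float = -30.0
    fatty_high: float = 29.0
    lean_low: float = 30.0
    lean_high: float = 100.0

    def __post_init__(self):
        if not self.fatty_high < self.lean_low:
            raise ValueError("fatty band must end below the lean band")
        if self.fatty_low > self.fatty_high or self.lean_low > self.lean_high:
            raise ValueError("threshold bands must be non-empty")

    def classify(self, hu: np.ndarray) -> np.ndarray:
        """Label array: 0 excluded, 1 fatty, 2 lean.

        Integer-valued grids use the inclusive bounds directly.  Float
        grids use fatty = [fatty_low, lean_low) and lean = [lean_low,
        lean_high] so no value falls in the gap between the bands.
        """
        hu = np.asarray(hu)
        lean = (hu >= self.lean_low) & (hu <= self.lean_high)
        if np.issubdtype(hu.dtype, np.integer):
            fatty = (hu >= self.fatty_low) & (hu <= self.fatty_high)
        else:
            fatty = (hu >= self.fatty_low) & (hu < self.lean_low)
        labels = np.zeros(hu.shape, dtype=np.uint8)
        labels[fatty] = 1
        labels[lean] = 2
        return labels


@dataclass(frozen=True)
class PixelCounts:
    """Per-class pixel counts for one compartment plus HU sums."""

    compartment: int
    fatty: int
    lean: int
    hu_sum_muscle: float
    hu_sum_compartment: float = float("nan")

    @property
    def muscle(self) -> int:
        return self.fatty + self.lean

    @property
    def excluded(self) -> int:
        return self.compartment - self.muscle


def classify_pixels(
    ct: CTSlice, mask: np.ndarray, thresholds: Thresholds | None = None
) -> PixelCounts:
    """Count fatty/lean/excluded pixels inside a compartment mask.

    Every masked pixel gets exactly one label; pixels outside both bands
    count toward the compartment area only.

    Raises
    ------
    ValueError : empty mask, or mask not congruent with the slice.
    """
    thresholds = thresholds or Thresholds()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ct.shape:
        raise ValueError(f"mask shape {mask.shape} != slice shape {ct.shape}")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no compartment pixels (empty mask)")
    hu = ct.hu[mask]
    labels = thresholds.classify(hu)
    fatty = int(np.count_nonzero(labels == 1))
    lean = int(np.count_nonzero(labels == 2))
    hu_sum = float(hu[labels > 0].sum())
    return PixelCounts(
        compartment=n,
        fatty=fatty,
        lean=lean,
        hu_sum_muscle=hu_sum,
        hu_sum_compartment=float(hu.sum()),
    )


@dataclass(frozen=True)
class CompositionResult:
    """Areas, FFMF and mean attenuation for one compartment (or a union).

    Areas are in cm^2; ``ffmf_percent`` = 100 * lean / (lean + fatty) on
    areas (equivalently pixel counts); ``mean_attenuation_hu`` averages HU
    over muscle (lean + fatty) pixels only.
    """

    side: Side
    counts: PixelCounts
    compartment_area_cm2: float
    muscle_area_cm2: float
    lean_area_cm2: float
    fatty_area_cm2: float
    ffmf_percent: float
    mean_attenuation_hu: float

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "compartment_pixels": self.counts.compartment,
            "fatty_pixels": self.counts.fatty,
            "lean_pixels": self.counts.lean,
            "excluded_pixels": self.counts.excluded,
            "compartment_area_cm2": self.compartment_area_cm2,
            "muscle_area_cm2": self.muscle_area_cm2,
            "lean_area_cm2": self.lean_area_cm2,
            "fatty_area_cm2": self.fatty_area_cm2,
            "ffmf_percent": self.ffmf_percent,
            "mean_attenuation_hu": self.mean_attenuation_hu,
        }


def compute_composition(
    counts: PixelCounts,
    pixel_spacing_mm: tuple[float, float],
    side: Side = "combined",
    attenuation_over: Literal["muscle", "compartment"] = "muscle",
) -> CompositionResult:
    """Turn pixel counts into areas (cm^2), FFMF (%) and mean attenuation.

    Area per pixel is row_spacing * col_spacing in mm^2; cm^2 = mm^2 / 100.
    ``attenuation_over`` selects the averaging region for mean attenuation:
    muscle pixels only (default) or the whole traced compartment.

    Raises
    ------
    ValueError : if no muscle pixels exist (FFMF undefined, not 0).
    """
    rs, cs = pixel_spacing_mm
    if not (rs > 0 and cs > 0):
        raise ValueError("pixel spacing must be > 0")
    if min(counts.compartment, counts.fatty, counts.lean) < 0:
        raise ValueError("pixel counts must be >= 0")
    if counts.muscle == 0:
        raise ValueError(
            "no muscle pixels in compartment: FFMF undefined "
            "(all pixels outside the fatty and lean HU bands)"
        )
    px_cm2 = rs * cs / 100.0
    lean_area = counts.lean * px_cm2
    fatty_area = counts.fatty * px_cm2
    if attenuation_over == "muscle":
        mean_hu = counts.hu_sum_muscle / counts.muscle
    elif attenuation_over == "compartment":
        mean_hu = counts.hu_sum_compartment / counts.compartment
    else:
        raise ValueError("attenuation_over must be 'muscle' or 'compartment'")
    return CompositionResult(
        side=side,
        counts=counts,
        compartment_area_cm2=counts.compartment * px_cm2,
        muscle_area_cm2=(counts.lean + counts.fatty) * px_cm2,
        lean_area_cm2=lean_area,
        fatty_area_cm2=fatty_area,
        ffmf_percent=100.0 * counts.lean / counts.muscle,
        mean_attenuation_hu=mean_hu,
    )


def compose_slice(
    ct: CTSlice,
    left: CompartmentROI,
    right: CompartmentROI,
    thresholds: Thresholds | None = None,
) -> tuple[CompositionResult, CompositionResult, CompositionResult]:
    """Score both paraspinal compartments and their union.

    Returns ``(combined, left_result, right_result)``.  The combined
    result is computed on the union of the two masks; per-side counts add
    up to the combined counts because the ROIs must be disjoint.

    Raises
    ------
    ValueError : overlapping ROIs.
    """
    thresholds = thresholds or Thresholds()
    lmask = left.to_mask(ct)
    rmask = right.to_mask(ct)
    if np.any(lmask & rmask):
        n_overlap = int(np.count_nonzero(lmask & rmask))
        raise ValueError(f"left and right ROIs overlap in {n_overlap} pixels")
    lcounts = classify_pixels(ct, lmask, thresholds)
    rcounts = classify_pixels(ct, rmask, thresholds)
    combined = PixelCounts(
        compartment=lcounts.compartment + rcounts.compartment,
        fatty=lcounts.fatty + rcounts.fatty,
        lean=lcounts.lean + rcounts.lean,
        hu_sum_muscle=lcounts.hu_sum_muscle + rcounts.hu_sum_muscle,
        hu_sum_compartment=lcounts.hu_sum_compartment + rcounts.hu_sum_compartment,
    )
    return (
        compute_composition(combined, ct.pixel_spacing_mm, "combined"),
        compute_composition(lcounts, ct.pixel_spacing_mm, "left"),
        compute_composition(rcounts, ct.pixel_spacing_mm, "right"),
    )
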