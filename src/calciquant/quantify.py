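"""Lesion quantification: bone subtraction, region growing, areas and axes.

Once the phalanges are segmented they are subtracted from the image
(masked to the background floor, with a small dilation margin so the
partial-intensity rim at the bone boundary cannot seed false lesions), and
the residual bright blobs — the calcified lesions — are delineated by
seeded region growing. Each lesion is then measured two ways:

* pixel-count area: ``n_pixels * spacing**2`` in mm²;
* the radiologists' ellipse estimate: maximal long axis, maximal
  perpendicular short axis, and area ``(long/2) * (short/2) * π``.

The long axis is the maximum Feret diameter over foreground pixel centers;
the short axis is the extent of the projection onto the perpendicular
direction. Distances are between pixel centers, so a single-pixel lesion has
zero axes and is flagged degenerate rather than given an artificial floor.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import BinaryMask, ImageGrid
from .segment import VisibilityReport, check_visibility

__all__ = [
    "RegionGrowParams",
    "LesionMeasurement",
    "QuantificationResult",
    "AxisMeasurement",
    "subtract_bone",
    "region_grow",
    "lesion_area",
    "measure_axes",
    "ellipse_area",
    "ellipsoid_volume",
    "quantify_image",
    "measurements_to_frame",
]

_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass(frozen=True)
class RegionGrowParams:
    """Parameters of the seeded region-growing lesion delineation.

    intensity_threshold : minimum intensity for seed candidacy and admission
    tolerance : admission band around the running region mean
    connectivity : 4 or 8 neighbourhood
    min_lesion_px : regions smaller than this are discarded as specks
    bone_dilation_px : exclusion margin applied around bone at subtraction
    """

    intensity_threshold: float = 600.0
    tolerance: float = 150.0
    connectivity: int = 8
    min_lesion_px: int = 3
    bone_dilation_px: int = 1

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.min_lesion_px < 1:
            raise ValueError("min_lesion_px must be >= 1")
        if self.bone_dilation_px < 0:
            raise ValueError("bone_dilation_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class AxisMeasurement:
    long_mm: float
    short_mm: float
    degenerate: bool

    def __iter__(self):  # allows `long, short = measure_axes(...)` style use
        yield self.long_mm
        yield self.short_mm


@dataclass(frozen=True)
class LesionMeasurement:
    """Per-lesion measurements in physical units."""

    lesion_id: int
    pixel_count: int
    area_mm2: float
    long_axis_mm: float
    short_axis_mm: float
    ellipse_area_mm2: float
    centroid: tuple[float, float]  # (row, col) in pixels
    degenerate: bool

    def __post_init__(self) -> None:
        if not (self.long_axis_mm >= self.short_axis_mm >= 0):
            raise ValueError("axes must satisfy long >= short >= 0")


@dataclass(frozen=True)
class QuantificationResult:
    """Either a list of lesion measurements or a visibility-failure marker."""

    visibility: VisibilityReport
    measurements: tuple[LesionMeasurement, ...] | None

    @property
    def complete(self) -> bool:
        return self.visibility.complete


def subtract_bone(image: ImageGrid, bone_mask: BinaryMask, dilation_px: int = 1) -> ImageGrid:
    """Mask out the segmented bone (dilated by ``dilation_px``) to the background floor."""
    bone_mask.check_aligned(image)
    if dilation_px < 0:
        raise ValueError("dilation_px must be >= 0")
    excl = bone_mask.pixels
    if dilation_px > 0 and excl.any():
        excl = ndimage.binary_dilation(excl, structure=np.ones((3, 3), bool), iterations=dilation_px)
    floor = float(image.pixels.min())
    out = np.where(excl, floor, image.pixels)
    return ImageGrid(out, image.spacing)


def region_grow(residual: ImageGrid, params: RegionGrowParams) -> list[BinaryMask]:
    """Delineate bright residual lesions by seeded region growing.

    Seeds are local intensity maxima at or above ``intensity_threshold``
    (3x3 neighbourhood, plateaus included), visited in order of descending
    intensity. Each region grows breadth-first, admitting a neighbouring
    pixel iff its intensity is at or above the threshold and within
    ``tolerance`` of the running region mean (updated incrementally). Grown
    pixels are claimed globally, so returned masks are pairwise disjoint.
    Regions below ``min_lesion_px`` are dropped. Output is ordered by
    descending pixel count, ties broken by centroid (row, col).

    With ``tolerance = inf`` this reduces exactly to connected-component
    labelling of the thresholded raster.
    """
    img = residual.pixels
    thr = params.intensity_threshold
    above = img >= thr
    # seed detection uses the growth connectivity's neighbourhood so that
    # every connected component above threshold contains at least one seed
    footprint = (
        np.ones((3, 3), bool)
        if params.connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    local_max = (img == ndimage.maximum_filter(img, footprint=footprint)) & above
    seeds = np.argwhere(local_max)
    if len(seeds) == 0:
        return []
    order = np.lexsort((seeds[:, 1], seeds[:, 0], -img[seeds[:, 0], seeds[:, 1]]))
    seeds = seeds[order]

    offsets = _OFFSETS_8 if params.connectivity == 8 else _OFFSETS_4
    h, w = img.shape
    claimed = np.zeros((h, w), dtype=bool)
    regions: list[np.ndarray] = []
    for sr, sc in seeds:
        if claimed[sr, sc]:
            continue
        region = np.zeros((h, w), dtype=bool)
        region[sr, sc] = True
        claimed[sr, sc] = True
        total = float(img[sr, sc])
        count = 1
        queue = deque([(int(sr), int(sc))])
        while queue:
            r, c = queue.popleft()
            mean = total / count
            for dr, dc in offsets:
                nr, nc = r + dr, c + dc
                if not (0 <= nr < h and 0 <= nc < w):
                    continue
                if claimed[nr, nc] or not above[nr, nc]:
                    continue
                if abs(img[nr, nc] - mean) <= params.tolerance:
                    region[nr, nc] = True
                    claimed[nr, nc] = True
                    total += float(img[nr, nc])
                    count += 1
                    queue.append((nr, nc))
        if count >= params.min_lesion_px:
            regions.append(region)
        # pixels of discarded specks stay claimed: they are noise, not lesion

    def sort_key(m: np.ndarray):
        pts = np.argwhere(m)
        cr, cc = pts.mean(axis=0)
        return (-int(m.sum()), float(cr), float(cc))

    regions.sort(key=sort_key)
    return [BinaryMask(m, residual.spacing) for m in regions]


def lesion_area(mask: BinaryMask) -> float:
    """Pixel-count area in mm²: ``n_pixels * spacing**2``."""
    return mask.n_pixels * mask.spacing**2


def _max_distance_pair(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Deterministic maximal-distance pair over point rows (lexicographic tie-break)."""
    if len(pts) > 2000:
        # exact reduction: the farthest pair lies on the convex hull
        try:
            from scipy.spatial import ConvexHull

            hull = ConvexHull(pts)
            pts = pts[np.sort(hull.vertices)]
        except Exception:
            pass  # degenerate (e.g. collinear) input: brute-force below
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    best = d2.max()
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)  # first pair in scan order
    return pts[i], pts[j], float(np.sqrt(best))


def measure_axes(mask: BinaryMask) -> AxisMeasurement:
    """Maximal long axis and maximal perpendicular short axis in mm.

    Long axis: maximum Feret diameter over pixel centers. Short axis: extent
    of the projection of all pixel centers onto the direction perpendicular
    to the long axis. Exact (brute-force equivalent), deterministic.
    """
    pts = np.argwhere(mask.pixels).astype(float)
    if len(pts) == 0:
        raise ValueError("cannot measure axes of an empty mask")
    s = mask.spacing
    if len(pts) == 1:
        return AxisMeasurement(0.0, 0.0, True)
    p, q, dist = _max_distance_pair(pts)
    if dist == 0.0:
        return AxisMeasurement(0.0, 0.0, True)
    direction = (q - p) / dist
    perp = np.array([-direction[1], direction[0]])
    proj = pts @ perp
    # the extent of a projection cannot exceed the maximal pairwise distance;
    # the min() guards against ulp-level excess (e.g. a 2x2 pixel square)
    short = min(float(proj.max() - proj.min()), dist)
    return AxisMeasurement(dist * s, short * s, degenerate=(short == 0.0))


def ellipse_area(long_axis_mm: float, short_axis_mm: float) -> float:
    """Radiologists' elliptical area estimate: (long/2) x (short/2) x π."""
    if short_axis_mm < 0:
        raise ValueError("axes must be >= 0")
    if long_axis_mm < short_axis_mm:
        raise ValueError("long axis must be >= short axis")
    return (long_axis_mm / 2.0) * (short_axis_mm / 2.0) * np.pi


def ellipsoid_volume(d1_mm: float, d2_mm: float, d3_mm: float) -> float:
    """Ellipsoid volume from three orthogonal diameters: (π/6) d1 d2 d3.

    π/6 ≈ 0.52 is the conventional multiplication factor used in clinical
    volume estimation from three axis measurements.
    """
    if d1_mm < 0 or d2_mm < 0 or d3_mm < 0:
        raise ValueError("diameters must be >= 0")
    return (np.pi / 6.0) * d1_mm * d2_mm * d3_mm


def quantify_image(
    image: ImageGrid,
    bone_mask: BinaryMask,
    params: RegionGrowParams,
    expected_components: int = 3,
    border_margin_px: int = 1,
) -> QuantificationResult:
    """Full per-image quantification stage.

    Runs the phalange-visibility check first; incomplete images yield a
    failure marker (``measurements is None``) and must be excluded from
    analysis. Otherwise: subtract bone, region-grow the residual, and
    assemble per-lesion measurements.
    """
    bone_mask.check_aligned(image)
    visibility = check_visibility(bone_mask, expected_components, border_margin_px)
    if not visibility.complete:
        return QuantificationResult(visibility=visibility, measurements=None)
    residual = subtract_bone(image, bone_mask, params.bone_dilation_px)
    masks = region_grow(residual, params)
    measurements = []
    for i, m in enumerate(masks):
        axes = measure_axes(m)
        pts = np.argwhere(m.pixels)
        measurements.append(
            LesionMeasurement(
                lesion_id=i,
                pixel_count=m.n_pixels,
                area_mm2=lesion_area(m),
                long_axis_mm=axes.long_mm,
                short_axis_mm=axes.short_mm,
                ellipse_area_mm2=ellipse_area(axes.long_mm, axes.short_mm),
                centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                degenerate=axes.degenerate,
            )
        )
    return QuantificationResult(visibility=visibility, measurements=tuple(measurements))


def measurements_to_frame(
    results: dict[str, QuantificationResult]
) -> pd.DataFrame:
    """Tabulate per-lesion rows across images (one row per lesion).

    Columns follow the pipeline's CSV contract; images that failed the
    visibility check contribute a single row with ``visibility_complete``
    False and no measurements.
    """
    rows = []
    for image_id, res in results.items():
        if res.measurements is None:
            rows.append(
                {
                    "image_id": image_id,
                    "lesion_id": pd.NA,
                    "pixel_count": pd.NA,
                    "area_mm2": np.nan,
                    "long_axis_mm": np.nan,
                    "short_axis_mm": np.nan,
                    "ellipse_area_mm2": np.nan,
                    "degenerate": pd.NA,
                    "visibility_complete": False,
                }
            )
            continue
        for m in res.measurements:
            rows.append(
                {
                    "image_id": image_id,
                    "lesion_id": m.lesion_id,
                    "pixel_count": m.pixel_count,
                    "area_mm2": m.area_mm2,
                    "long_axis_mm": m.long_axis_mm,
                    "short_axis_mm": m.short_axis_mm,
                    "ellipse_area_mm2": m.ellipse_area_mm2,
                    "degenerate": m.degenerate,
                    "visibility_complete": True,
                }
            )
    return pd.DataFrame(rows)
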