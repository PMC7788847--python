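"""Synthetic finger phantoms with known ground truth.

Real bone-window DECT finger images show three bright elongated phalanges
separated by joint spaces, with calcinosis cutis (CC) lesions appearing as
irregular bright blobs in the adjacent soft tissue. Because bone and CC
deposits are both calcium hydroxyapatite, their intensities overlap — which
is exactly why lesions cannot be isolated by thresholding alone and a bone
segmentation step is required. The phantom generator reproduces this
geometry and difficulty on a small raster with pixel-exact ground truth:

* ``n_phalanges`` capsule-shaped bone segments laid end-to-end along the
  image's vertical axis, with gaps playing the role of joint spaces;
* 0–3 star-convex, irregularly shaped lesions placed adjacent to bone but
  disjoint from it (every lesion pixel sits at least 2 px from bone, and at
  least one sits exactly at that distance, so a 1-px bone exclusion margin
  during subtraction never erodes a lesion);
* additive Gaussian noise applied last; ground-truth masks stay noise-free.

Intensities are pseudo-HU and rounded to integers so images round-trip
losslessly through 16-bit TIFF.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as PILImage
from scipy import ndimage

from .grids import BinaryMask, ImageGrid

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "PlacementError",
    "MetadataMissingError",
    "generate_phantom",
    "generate_phantoms",
    "rotate_augment",
    "apply_window",
    "write_dataset",
    "read_dataset",
]


class PlacementError(RuntimeError):
    """Raised when a lesion cannot be placed without violating geometry constraints."""


class MetadataMissingError(FileNotFoundError):
    """Raised when a sample directory lacks its JSON metadata sidecar."""


# Minimum euclidean distance (px) from any lesion pixel to bone. Chosen so the
# default 1-px bone exclusion margin (a 3x3 dilation reaches at most sqrt(2) px)
# can never remove true lesion pixels, while "adjacent to bone" still holds.
_LESION_BONE_GAP_PX = 2.0
_LESION_MIN_PX = 12
_MAX_PLACEMENT_ATTEMPTS = 300


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic finger image.

    Defaults emulate a sagittal bone-window finger view at desk scale:
    a 64x64 raster at 0.25 mm/pixel (a 16x16 mm field of view), three
    phalanges, and lesions whose intensity overlaps the bone intensity.
    """

    height: int = 64
    width: int = 64
    spacing: float = 0.25
    n_phalanges: int = 3
    bone_intensity: float = 1200.0
    lesion_intensity: float = 1150.0
    background_intensity: float = 50.0
    noise_sd: float = 30.0
    n_lesions: int = 2
    lesion_radius_range: tuple[float, float] = (0.8, 1.5)  # mm
    lesion_irregularity: float = 0.4
    truncate_phalanges: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("phantom must be at least 16x16 pixels")
        if not (self.spacing > 0):
            raise ValueError("spacing must be > 0")
        if self.n_phalanges < 1:
            raise ValueError("n_phalanges must be >= 1")
        if not (0 <= self.n_lesions <= 3):
            raise ValueError("n_lesions must be in 0..3")
        if not (self.lesion_intensity > self.background_intensity):
            raise ValueError("lesion_intensity must exceed background_intensity")
        if not (self.bone_intensity > self.background_intensity):
            raise ValueError("bone_intensity must exceed background_intensity")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range must satisfy 0 < min <= max")
        if not (0.0 <= self.lesion_irregularity <= 1.0):
            raise ValueError("lesion_irregularity must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PhantomSample:
    """A generated image plus its noise-free ground truth."""

    image: ImageGrid
    bone_mask: BinaryMask
    lesion_masks: tuple[BinaryMask, ...]
    true_areas: tuple[float, ...]
    spec: PhantomSpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesion_masks", tuple(self.lesion_masks))
        object.__setattr__(self, "true_areas", tuple(float(a) for a in self.true_areas))
        if len(self.lesion_masks) != len(self.true_areas):
            raise ValueError("one true area per lesion mask required")
        self.bone_mask.check_aligned(self.image)
        s2 = self.image.spacing ** 2
        for mask, area in zip(self.lesion_masks, self.true_areas):
            mask.check_aligned(self.image)
            if mask.pixels[self.bone_mask.pixels].any():
                raise ValueError("lesion mask overlaps bone mask")
            if abs(area - mask.n_pixels * s2) > 1e-9:
                raise ValueError("true_area inconsistent with mask pixel count x spacing^2")


def _capsule(shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray, half_width: float) -> np.ndarray:
    """Boolean raster of pixels whose centers lie within half_width of segment p0-p1."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.stack([rr, cc], axis=-1).astype(float)
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0.0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / len2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    return dist <= half_width


def _bone_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Capsule phalanges end-to-end along the row axis, distal ones thinner."""
    h, w = spec.height, spec.width
    margin = max(5, h // 12)
    top = float(margin + rng.uniform(0, 2))
    bottom = float(h - margin - rng.uniform(0, 2))
    if spec.truncate_phalanges:
        # shift the column upward so the first phalange is clipped by the border
        shift = top + 0.35 * (bottom - top)
        top -= shift
        bottom -= shift
    col0 = w / 2 + rng.uniform(-2.5, 2.5)
    tilt = rng.uniform(-0.06, 0.06)  # radians; slight off-axis finger pose
    gap = max(3.0, h / 21)
    n = spec.n_phalanges
    # proximal-to-distal length weights, mimicking real phalanx proportions
    weights = np.linspace(1.5, 1.0, n)
    weights /= weights.sum()
    usable = (bottom - top) - gap * (n - 1)
    if usable < 4 * n:
        raise ValueError("raster too small for the requested phalange layout")
    mask = np.zeros((h, w), dtype=bool)
    row = top
    base_hw = min(w / 14.0, 5.0)
    for i in range(n):
        seg_len = usable * weights[i]
        half_width = base_hw * (1.0 - 0.18 * i / max(n - 1, 1)) + rng.uniform(-0.3, 0.3)
        # inset the segment by half_width so the rounded caps stay inside
        # [row, row + seg_len] and joint gaps are preserved
        inset = min(half_width, seg_len / 2 - 1)
        a = row + inset
        b = row + seg_len - inset
        r0 = np.array([a, col0 + np.tan(tilt) * (a - h / 2)])
        r1 = np.array([b, col0 + np.tan(tilt) * (b - h / 2)])
        mask |= _capsule((h, w), r0, r1, half_width)
        row += seg_len + gap
    return mask


def _star_polygon(
    center: np.ndarray, radius_px: float, irregularity: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vertices (rows, cols) of a random star-convex polygon around center."""
    n_vert = int(rng.integers(7, 12))
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
    radii = radius_px * (1.0 + irregularity * rng.uniform(-0.5, 0.5, n_vert))
    rows = center[0] + radii * np.sin(angles)
    cols = center[1] + radii * np.cos(angles)
    return rows, cols


def _rasterize_polygon(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.draw import polygon

    rr, cc = polygon(rows, cols, shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def _place_lesions(
    spec: PhantomSpec, bone: np.ndarray, rng: np.random.Generator
) -> list[np.ndarray]:
    dist_to_bone = ndimage.distance_transform_edt(~bone)
    grad_r, grad_c = np.gradient(dist_to_bone)
    allowed = dist_to_bone >= _LESION_BONE_GAP_PX
    lesions: list[np.ndarray] = []
    blocked = np.zeros_like(bone)  # existing lesions dilated, keeps lesions separable
    lo_px = spec.lesion_radius_range[0] / spec.spacing
    hi_px = spec.lesion_radius_range[1] / spec.spacing
    for _ in range(spec.n_lesions):
        placed = False
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            ring = np.argwhere(
                (dist_to_bone >= _LESION_BONE_GAP_PX)
                & (dist_to_bone <= _LESION_BONE_GAP_PX + 1.5)
                & ~blocked
            )
            if len(ring) == 0:
                break
            anchor = ring[rng.integers(len(ring))].astype(float)
            radius = rng.uniform(lo_px, hi_px)
            g = np.array([grad_r[int(anchor[0]), int(anchor[1])], grad_c[int(anchor[0]), int(anchor[1])]])
            norm = np.linalg.norm(g)
            direction = g / norm if norm > 0 else np.array([0.0, 1.0])
            center = anchor + direction * (0.6 * radius)
            rows, cols = _star_polygon(center, radius, spec.lesion_irregularity, rng)
            cand = _rasterize_polygon(rows, cols, bone.shape) & allowed & ~blocked
            cand = _largest_component(cand)
            if cand.sum() < _LESION_MIN_PX:
                continue
            min_dist = dist_to_bone[cand].min()
            if min_dist > _LESION_BONE_GAP_PX + 1e-9:
                continue  # not adjacent to bone
            lesions.append(cand)
            blocked |= ndimage.binary_dilation(cand, iterations=3)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place lesion {len(lesions) + 1} of {spec.n_lesions} "
                f"after {_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    return lesions


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom sample. Deterministic for a fixed ``spec.seed``.

    Raises
    ------
    PlacementError
        If a lesion cannot be placed adjacent to (but disjoint from) bone
        within a bounded number of attempts.
    """
    rng = np.random.default_rng(spec.seed)
    bone = _bone_mask(spec, rng)
    lesions = _place_lesions(spec, bone, rng)

    img = np.full((spec.height, spec.width), spec.background_intensity, dtype=np.float64)
    img[bone] = spec.bone_intensity
    for les in lesions:
        img[les] = spec.lesion_intensity
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.round(img)  # integer pseudo-HU, lossless in 16-bit TIFF

    s = spec.spacing
    sample = PhantomSample(
        image=ImageGrid(img, s),
        bone_mask=BinaryMask(bone, s),
        lesion_masks=tuple(BinaryMask(m, s) for m in lesions),
        true_areas=tuple(float(m.sum()) * s * s for m in lesions),
        spec=spec,
    )
    return sample


def generate_phantoms(
    n: int, base_seed: int = 0, base_spec: PhantomSpec | None = None
) -> list[PhantomSample]:
    """Generate ``n`` phantoms with per-sample seeds derived from ``base_seed``."""
    base = base_spec if base_spec is not None else PhantomSpec()
    seeds = np.random.SeedSequence(base_seed).generate_state(n) % (2**31 - 1)
    out = []
    for i in range(n):
        spec = dataclasses.replace(base, seed=int(seeds[i]))
        out.append(generate_phantom(spec))
    return out


def rotate_augment(
    pairs: list[tuple[ImageGrid, BinaryMask]],
    n_rotations: int,
    angles: list[float] | None = None,
) -> list[tuple[ImageGrid, BinaryMask]]:
    """Expand an image/mask training set by joint spatial rotation.

    Originals are preserved at the head of the output, followed by all
    rotated copies; the output has ``len(pairs) * (1 + n_rotations)``
    elements. By default the rotations are the lossless quarter-turns
    (90, 180, 270 degrees), which keep masks bit-exact on a square raster;
    arbitrary ``angles`` (degrees) are available with bilinear image and
    nearest-neighbour mask resampling.
    """
    if n_rotations < 0:
        raise ValueError("n_rotations must be >= 0")
    if angles is None:
        if n_rotations > 3:
            raise ValueError(
                "default quarter-turn augmentation supports n_rotations <= 3; "
                "pass explicit angles for more"
            )
        angles_used: list[float] = [90.0 * (k + 1) for k in range(n_rotations)]
        exact = True
    else:
        if len(angles) != n_rotations:
            raise ValueError("len(angles) must equal n_rotations")
        angles_used = list(angles)
        exact = all(a % 90 == 0 for a in angles_used)

    out = list(pairs)
    for angle in angles_used:
        for image, mask in pairs:
            mask.check_aligned(image)
            if exact:
                k = int(angle // 90) % 4
                img_px = np.rot90(image.pixels, k=k)
                msk_px = np.rot90(mask.pixels, k=k)
            else:
                img_px = ndimage.rotate(image.pixels, angle, reshape=False, order=1, mode="nearest")
                msk_px = ndimage.rotate(
                    mask.pixels.astype(np.uint8), angle, reshape=False, order=0, mode="constant"
                ).astype(bool)
            out.append((ImageGrid(img_px.copy(), image.spacing), BinaryMask(msk_px.copy(), mask.spacing)))
    return out


def apply_window(image: ImageGrid, window: float, level: float) -> ImageGrid:
    """Radiology window/level display mapping onto [0, 1].

    Intensities at or below ``level - window/2`` map to 0, at or above
    ``level + window/2`` map to 1, linearly in between. The bone-optimised
    setting for these images is window 1500, level 450.
    """
    if not (window > 0):
        raise ValueError("window must be > 0")
    lo = level - window / 2.0
    scaled = np.clip((image.pixels - lo) / window, 0.0, 1.0)
    return ImageGrid(scaled, image.spacing)


# ---------------------------------------------------------------------------
# Dataset I/O: 16-bit TIFF images, {0,255} PNG masks, one JSON sidecar each.
# ---------------------------------------------------------------------------

_META_NAME = "meta.json"


def _write_mask_png(path: Path, mask: BinaryMask) -> None:
    arr = np.where(mask.pixels, 255, 0).astype(np.uint8)
    PILImage.fromarray(arr, mode="L").save(path)


def _read_mask_png(path: Path, spacing: float) -> BinaryMask:
    arr = np.asarray(PILImage.open(path))
    return BinaryMask(arr >= 128, spacing)


def write_dataset(samples: list[PhantomSample], directory: str | Path) -> None:
    """Write samples as TIFF/PNG rasters with one JSON metadata sidecar each."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, sample in enumerate(samples):
        d = directory / f"sample_{i:04d}"
        d.mkdir(exist_ok=True)
        px = sample.image.pixels
        if np.array_equal(px, np.round(px)) and px.min() >= -32768 and px.max() <= 32767:
            tifffile.imwrite(d / "image.tif", px.astype(np.int16))
        else:
            tifffile.imwrite(d / "image.tif", px.astype(np.float32))
        _write_mask_png(d / "bone_mask.png", sample.bone_mask)
        for j, lm in enumerate(sample.lesion_masks):
            _write_mask_png(d / f"lesion_{j:02d}.png", lm)
        meta = {
            "spacing_mm": sample.image.spacing,
            "n_lesions": len(sample.lesion_masks),
            "true_areas_mm2": list(sample.true_areas),
            "truncated": sample.spec.truncate_phalanges,
            "seed": sample.spec.seed,
            "spec": dataclasses.asdict(sample.spec),
        }
        (d / _META_NAME).write_text(json.dumps(meta, indent=1))


def read_dataset(directory: str | Path) -> list[PhantomSample]:
    """Read samples written by :func:`write_dataset` (lossless round-trip)."""
    directory = Path(directory)
    out = []
    for d in sorted(p for p in directory.iterdir() if p.is_dir()):
        meta_path = d / _META_NAME
        if not meta_path.exists():
            raise MetadataMissingError(f"missing {_META_NAME} sidecar in {d}")
        meta = json.loads(meta_path.read_text())
        spacing = float(meta["spacing_mm"])
        img = tifffile.imread(d / "image.tif").astype(np.float64)
        spec_dict = dict(meta["spec"])
        spec_dict["lesion_radius_range"] = tuple(spec_dict["lesion_radius_range"])
        spec = PhantomSpec(**spec_dict)
        bone = _read_mask_png(d / "bone_mask.png", spacing)
        if bone.shape != img.shape:
            raise ValueError(f"bone mask shape {bone.shape} does not match image {img.shape} in {d}")
        lesions = []
        for j in range(int(meta["n_lesions"])):
            lm = _read_mask_png(d / f"lesion_{j:02d}.png", spacing)
            if lm.shape != img.shape:
                raise ValueError(f"lesion mask shape mismatch in {d}")
            lesions.append(lm)
        out.append(
            PhantomSample(
                image=ImageGrid(img, spacing),
                bone_mask=bone,
                lesion_masks=tuple(lesions),
                true_areas=tuple(meta["true_areas_mm2"]),
                spec=spec,
            )
        )
    return out
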