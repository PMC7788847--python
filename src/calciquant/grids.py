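"""Shared raster containers: intensity images and binary masks with physical spacing.

Every stage of the pipeline — phantom generation, bone segmentation, lesion
quantification — exchanges these two types. Intensities are scalar
pseudo-Hounsfield units on an isotropic pixel grid; ``spacing`` is the edge
length of one pixel in millimetres, so one pixel covers ``spacing**2`` mm².
The coordinate convention is row-major with the origin at the top-left pixel
and 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid", "BinaryMask"]

_MIN_SIDE = 16


@dataclass(frozen=True)
class ImageGrid:
    """A 2D scalar intensity raster with isotropic mm/pixel spacing.

    Parameters
    ----------
    pixels : ndarray of shape (height, width)
        Scalar intensities, interpretable as pseudo-HU. Stored as float64.
    spacing : float
        Millimetres per pixel (isotropic, > 0).
    """

    pixels: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=np.float64)
        if pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got ndim={pixels.ndim}")
        if pixels.shape[0] < _MIN_SIDE or pixels.shape[1] < _MIN_SIDE:
            raise ValueError(
                f"image must be at least {_MIN_SIDE}x{_MIN_SIDE}, got {pixels.shape}"
            )
        if not np.all(np.isfinite(pixels)):
            raise ValueError("image intensities must all be finite")
        if not (float(self.spacing) > 0):
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "spacing", float(self.spacing))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def __eq__(self, other) -> bool:  # value semantics, used by dataset round-trips
        if not isinstance(other, ImageGrid):
            return NotImplemented
        return self.spacing == other.spacing and np.array_equal(self.pixels, other.pixels)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean raster aligned to an :class:`ImageGrid`."""

    pixels: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        if pixels.dtype != np.bool_:
            pixels = pixels.astype(bool)
        if pixels.ndim != 2:
            raise ValueError(f"mask must be 2D, got ndim={pixels.ndim}")
        if not (float(self.spacing) > 0):
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "spacing", float(self.spacing))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_pixels(self) -> int:
        """Number of foreground pixels."""
        return int(self.pixels.sum())

    def check_aligned(self, other: "ImageGrid | BinaryMask") -> None:
        """Raise ValueError unless ``other`` shares shape and spacing."""
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")
        if self.spacing != other.spacing:
            raise ValueError(f"spacing mismatch: {self.spacing} vs {other.spacing}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.spacing == other.spacing and np.array_equal(self.pixels, other.pixels)
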