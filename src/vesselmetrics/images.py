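"""Calibrated image containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class ParameterError(ValueError):
    """Invalid parameter supplied to an operation."""


class InputError(ValueError):
    """Invalid input data supplied to an operation."""


@dataclass
class CalibratedImage:
    """Intensity image with a physical pixel size.

    Parameters
    ----------
    pixels:
        2D ``(y, x)`` or 3D ``(z, y, x)`` intensity array.
    pixel_size:
        µm per pixel. A scalar for 2D images; for stacks either a scalar
        (isotropic) or a ``(z, y, x)`` triple.
    roi:
        Optional boolean region-of-interest mask with the same ``(y, x)``
        footprint as ``pixels``. Densities downstream are normalized to the
        ROI area, not the image area.
    center:
        Optional ``(x, y)`` pixel coordinate of the optic-nerve-head
        analogue, the origin for outgrowth measurements.
    metadata:
        Free-form provenance notes (warnings, generator parameters, ...).
    """

    pixels: np.ndarray
    pixel_size: float | tuple[float, float, float]
    roi: np.ndarray | None = None
    center: tuple[float, float] | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise InputError(f"expected a 2D or 3D array, got ndim={self.pixels.ndim}")
        if self.pixels.size == 0:
            raise InputError("empty image")
        if np.any(np.asarray(self.pixel_size, dtype=float) <= 0):
            raise ParameterError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.roi is not None:
            self.roi = np.asarray(self.roi).astype(bool)
            if self.roi.shape != self.footprint:
                raise InputError(
                    f"roi shape {self.roi.shape} does not match image footprint {self.footprint}"
                )
        if self.center is not None:
            x, y = self.center
            h, w = self.footprint
            if not (0 <= x < w and 0 <= y < h):
                raise InputError(f"center {self.center} outside image bounds {w}x{h}")

    @property
    def footprint(self) -> tuple[int, int]:
        """``(height, width)`` of one plane."""
        return self.pixels.shape[-2:]

    @property
    def is_stack(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def pixel_size_yx(self) -> float:
        """In-plane pixel size in µm/px (y and x are assumed equal)."""
        if np.isscalar(self.pixel_size):
            return float(self.pixel_size)
        return float(self.pixel_size[-1])

    @property
    def pixel_size_z(self) -> float:
        if np.isscalar(self.pixel_size):
            return float(self.pixel_size)
        return float(self.pixel_size[0])


@dataclass
class BinaryMask:
    """Binary vessel mask with calibration and optional ROI."""

    pixels: np.ndarray
    pixel_size: float
    roi: np.ndarray | None = None
    center: tuple[float, float] | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise InputError(f"BinaryMask must be 2D, got ndim={self.pixels.ndim}")
        if float(self.pixel_size) <= 0:
            raise ParameterError(f"pixel_size must be positive, got {self.pixel_size}")
        self.pixel_size = float(self.pixel_size)
        if self.roi is not None:
            self.roi = np.asarray(self.roi).astype(bool)
            if self.roi.shape != self.pixels.shape:
                raise InputError(
                    f"roi shape {self.roi.shape} does not match mask shape {self.pixels.shape}"
                )

    @property
    def roi_or_full(self) -> np.ndarray:
        """The ROI, defaulting to the whole frame."""
        if self.roi is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.roi

    def roi_area_mm2(self) -> float:
        """ROI area in mm²."""
        n = int(np.count_nonzero(self.roi_or_full))
        return n * (self.pixel_size**2) / 1e6
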