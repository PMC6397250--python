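"""Binarization of raw fluorescence images into clean vessel masks.

The chain mirrors the standard flatmount workflow: 8-bit conversion,
adaptive local-mean thresholding, a radius-0.5 median despeckle, and ROI
masking. Thresholding is local so that a slowly varying illumination field
(common in stitched flatmount mosaics) does not bias the vessel mask.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from vesselmetrics.images import BinaryMask, CalibratedImage, InputError, ParameterError

# plus-shaped (radius 0.5) neighborhood: center + 4-neighbors
_PLUS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def to_8bit(image: CalibratedImage) -> CalibratedImage:
    """Linearly rescale intensities to the full 8-bit range.

    ``v -> (v - min) / (max - min) * 255``, rounded half away from zero.
    A constant image maps to all zeros.
    """
    px = np.asarray(image.pixels, dtype=np.float64)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        out = np.zeros(px.shape, dtype=np.uint8)
    else:
        scaled = (px - lo) / (hi - lo) * 255.0
        out = np.floor(scaled + 0.5).astype(np.uint8)
    return CalibratedImage(
        out, image.pixel_size, roi=image.roi, center=image.center, metadata=dict(image.metadata)
    )


def adaptive_threshold(
    image: CalibratedImage, window_px: int = 51, offset: float = 10.0
) -> BinaryMask:
    """Local-mean adaptive threshold of an 8-bit image.

    A pixel is foreground iff its intensity exceeds the mean over the
    surrounding ``window_px``-square window (edge-replicated) by more than
    ``offset``. A positive offset therefore suppresses flat background:
    a constant image yields an empty mask, and the offset sets how far a
    vessel must rise above its local surround to be kept.

    Parameters
    ----------
    image:
        2D 8-bit image.
    window_px:
        Odd window side length in pixels, >= 3. Should exceed the widest
        vessel so that the local mean tracks background, not vessel cores.
    offset:
        Intensity margin added to the local mean.
    """
    if image.pixels.ndim != 2:
        raise InputError("adaptive_threshold expects a 2D image")
    if window_px < 3 or window_px % 2 == 0:
        raise ParameterError(f"window_px must be odd and >= 3, got {window_px}")
    px = np.asarray(image.pixels, dtype=np.float64)
    local_mean = ndimage.uniform_filter(px, size=window_px, mode="nearest")
    fg = px > local_mean + offset
    return BinaryMask(
        fg,
        image.pixel_size_yx,
        roi=image.roi,
        center=image.center,
        metadata=dict(image.metadata),
    )


def median_despeckle(mask: BinaryMask) -> BinaryMask:
    """Despeckle with a radius-0.5 (plus-shaped, 5-pixel) median filter.

    Majority vote over the pixel and its 4-neighbors: isolated single
    pixels are removed and single-pixel holes in solid regions are filled.
    Note the kernel erodes 1-px-wide *diagonal* lines (each pixel of such a
    line has at most one foreground cross-neighbor), so vessel strokes must
    be at least 2 px wide to survive; choose the pixel size accordingly.
    """
    filtered = ndimage.median_filter(
        mask.pixels.astype(np.uint8), footprint=_PLUS, mode="nearest"
    )
    return BinaryMask(
        filtered > 0,
        mask.pixel_size,
        roi=mask.roi,
        center=mask.center,
        metadata=dict(mask.metadata),
    )


def apply_roi(mask: BinaryMask, roi: np.ndarray) -> BinaryMask:
    """Clear foreground outside the region of interest.

    The ROI is attached to the result so that all downstream densities are
    normalized by ROI area rather than image area.
    """
    roi = np.asarray(roi).astype(bool)
    if roi.shape != mask.pixels.shape:
        raise InputError(
            f"roi shape {roi.shape} does not match mask shape {mask.pixels.shape}"
        )
    if not roi.any():
        raise InputError("empty ROI")
    return BinaryMask(
        mask.pixels & roi,
        mask.pixel_size,
        roi=roi,
        center=mask.center,
        metadata=dict(mask.metadata),
    )


def binarize(
    image: CalibratedImage,
    window_px: int = 51,
    offset: float = 10.0,
    roi: np.ndarray | None = None,
) -> BinaryMask:
    """Full preprocessing chain: 8-bit -> adaptive threshold -> despeckle -> ROI."""
    mask = median_despeckle(adaptive_threshold(to_8bit(image), window_px, offset))
    roi = roi if roi is not None else image.roi
    if roi is not None:
        mask = apply_roi(mask, roi)
    return mask
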