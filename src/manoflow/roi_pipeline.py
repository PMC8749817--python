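"""Image preprocessing: margins, binarization, marker and ROI extraction.

Implements the five-step preprocessing the classifiers depend on, in order:

1. strip the instrument margins (15 px top, 120 px left, 30 px bottom);
2. binarize at grey-level 128 (Rec. 601 luma, inclusive threshold);
3. count white pixels per x-position (projection-profile histogram);
4. the histogram argmax is the swallow-marker column (ties -> smallest x);
5. crop the color image from that column to the right edge.

The swallow crop is the probe-positioning classifier input.  From the
binarized crop, the IRP region of interest is found bottom-up: the lowest
white pixel anchors a 100-px-tall, full-width band extending upward
(clamped and zero-padded at the top edge).  ``prepare_model_input``
produces the 299x299x3 tensor in [-1, 1] that the classification networks
consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from PIL import Image

from .topo_render import TopographyImage

TOP_MARGIN = 15
LEFT_MARGIN = 120
BOTTOM_MARGIN = 30
BINARIZE_THRESHOLD = 128
IRP_ROI_HEIGHT = 100
MODEL_INPUT_SIZE = 299

ImageLike = Union[np.ndarray, TopographyImage]


class DetectionError(RuntimeError):
    """The image contains no usable structure (all-black after binarization)."""


@dataclass(frozen=True)
class Roi:
    """Axis-aligned rectangle in image coordinates (top-left inclusive)."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0 or self.width < 1 or self.height < 1:
            raise ValueError(f"degenerate ROI {self}")


def _pixels(image: ImageLike) -> np.ndarray:
    arr = image.pixels if isinstance(image, TopographyImage) else np.asarray(image)
    if arr.ndim not in (2, 3) or arr.size == 0:
        raise ValueError("expected a non-empty 2-D or RGB image array")
    return arr


def strip_margins(image: ImageLike) -> np.ndarray:
    """Remove the 15/120/30 px instrument margins; the right edge is kept."""
    arr = _pixels(image)
    h, w = arr.shape[:2]
    if h <= TOP_MARGIN + BOTTOM_MARGIN or w <= LEFT_MARGIN:
        raise ValueError(
            f"image {h}x{w} too small to strip {TOP_MARGIN}/{LEFT_MARGIN}/"
            f"{BOTTOM_MARGIN} margins"
        )
    return arr[TOP_MARGIN : h - BOTTOM_MARGIN, LEFT_MARGIN:]


def luma(image: ImageLike) -> np.ndarray:
    """Rec. 601 grey level of an RGB (or already-grey) 8-bit image."""
    arr = _pixels(image)
    if arr.ndim == 2:
        return arr.astype(float)
    r, g, b = arr[..., 0].astype(float), arr[..., 1].astype(float), arr[..., 2].astype(float)
    # integer weights avoid 0.299+0.587+0.114 != 1 rounding at the threshold
    return (299.0 * r + 587.0 * g + 114.0 * b) / 1000.0


def binarize(image: ImageLike, threshold: int = BINARIZE_THRESHOLD) -> np.ndarray:
    """0/1 raster: 1 iff grey level >= threshold."""
    return (luma(image) >= threshold).astype(np.uint8)


def white_pixel_histogram(binary: np.ndarray) -> np.ndarray:
    """Number of white (1) pixels in each column; length = image width."""
    binary = np.asarray(binary)
    if binary.size == 0:
        raise ValueError("empty binary image")
    return binary.sum(axis=0).astype(np.int64)


def locate_swallow_line(binary: np.ndarray) -> int:
    """Column of the white swallow-marker line = histogram argmax.

    Ties break toward the smallest x. Raises DetectionError when the
    histogram is all zero (no white structure at all — unusable image).
    """
    hist = white_pixel_histogram(binary)
    if not hist.any():
        raise DetectionError("no white pixels: cannot locate the swallow line")
    return int(np.argmax(hist))


def crop_swallow(image: ImageLike, x: int) -> np.ndarray:
    """Columns [x, width) at full height: the single-swallow crop."""
    arr = _pixels(image)
    if not 0 <= x < arr.shape[1]:
        raise ValueError(f"crop column {x} outside [0, {arr.shape[1]})")
    return arr[:, x:]


def locate_irp_roi(binary_crop: np.ndarray, roi_height: int = IRP_ROI_HEIGHT) -> Roi:
    """Bottom-up ROI for the IRP classifier on the binarized swallow crop.

    The lowest white pixel (maximum row index holding a 1) anchors the
    band; the ROI spans rows [y* - roi_height + 1, y*] clamped at the top
    edge, across the full crop width.  When clamping shortens the band,
    ``extract_irp_roi`` zero-pads it back to ``roi_height`` rows.
    """
    binary_crop = np.asarray(binary_crop)
    rows_with_white = np.nonzero(binary_crop.any(axis=1))[0]
    if rows_with_white.size == 0:
        raise DetectionError("no white pixels: cannot anchor the IRP ROI")
    y_star = int(rows_with_white[-1])
    y0 = max(0, y_star - roi_height + 1)
    return Roi(x0=0, y0=y0, width=int(binary_crop.shape[1]), height=y_star - y0 + 1)


def extract_irp_roi(
    image: ImageLike, roi: Roi, roi_height: int = IRP_ROI_HEIGHT
) -> np.ndarray:
    """Cut the ROI out of the (color) crop, zero-padded on top to full height."""
    arr = _pixels(image)
    band = arr[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
    if band.shape[0] < roi_height:
        pad = np.zeros((roi_height - band.shape[0],) + band.shape[1:], dtype=arr.dtype)
        band = np.concatenate([pad, band], axis=0)
    return band


def prepare_model_input(image: ImageLike) -> np.ndarray:
    """Bilinear resize to 299x299 and map 8-bit values to [-1, 1]."""
    arr = _pixels(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    resized = Image.fromarray(arr.astype(np.uint8), mode="RGB").resize(
        (MODEL_INPUT_SIZE, MODEL_INPUT_SIZE), Image.BILINEAR
    )
    return np.asarray(resized, dtype=np.float32) / 127.5 - 1.0


def preprocess_image(
    raw: ImageLike,
    threshold: int = BINARIZE_THRESHOLD,
    roi_height: int = IRP_ROI_HEIGHT,
) -> dict:
    """Run the full five-step pipeline on one raw screen capture.

    Returns a dict with the detected ``marker_x`` (in stripped-image
    coordinates), the color ``swallow_crop``, the 100-px ``irp_roi`` band,
    the ``roi`` rectangle, and the two model-input tensors
    (``positioning_input`` from the crop, ``irp_input`` from the band).
    """
    stripped = strip_margins(raw)
    binary = binarize(stripped, threshold)
    x = locate_swallow_line(binary)
    crop = crop_swallow(stripped, x)
    binary_crop = binarize(crop, threshold)
    roi = locate_irp_roi(binary_crop, roi_height)
    band = extract_irp_roi(crop, roi, roi_height)
    return {
        "marker_x": x,
        "swallow_crop": crop,
        "irp_roi": band,
        "roi": roi,
        "positioning_input": prepare_model_input(crop),
        "irp_input": prepare_model_input(band),
    }
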