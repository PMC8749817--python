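"""Rendering of pressure recordings as 60-s color topography rasters.

Emulates the instrument screen capture the classifiers consume: the plot
area encodes pressure sensor-by-row (proximal at top, distal at bottom)
through a jet-like color scale, a white vertical line marks the wet
swallow, and grey instrument margins frame the plot (15 px top, 120 px
left, 30 px bottom — the values the ROI pipeline strips).

The color scale is piecewise linear in RGB over [-10, 150] mmHg and is
built so that its grey-level (Rec. 601 luma) crosses the 128 binarization
threshold exactly once, near 24 mmHg: every pressure above that maps to a
"white" pixel after binarization and everything below to "black".  This
guarantees the LES band (resting pressure ~30 mmHg) survives binarization
while the gastric and esophageal baselines do not, and keeps the marker
line (pure white, luma 255) the brightest element of the image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from PIL import Image

from .sim_pressure import PressureRecording, SwallowTruth

# colormap stops: pressure (mmHg) -> RGB; piecewise linear between stops.
# Luma at the stops: 5.5, 66.6, 126.0, 178.7, 225.9, 164.3, 130.1 —
# a single upward crossing of 128 between 24 and 30 mmHg.
COLOR_STOPS: Tuple[Tuple[float, Tuple[int, int, int]], ...] = (
    (-10.0, (0, 0, 48)),
    (15.0, (0, 64, 255)),
    (24.0, (0, 170, 230)),
    (30.0, (0, 255, 255)),
    (70.0, (255, 255, 0)),
    (110.0, (255, 150, 0)),
    (150.0, (255, 80, 60)),
)

GREY = (192, 192, 192)
WHITE = (255, 255, 255)


@dataclass(frozen=True)
class RenderSpec:
    """Raster geometry and appearance of the instrument screen capture."""

    image_width: int = 1000
    image_height: int = 600
    top_margin: int = 15
    left_margin: int = 120
    bottom_margin: int = 30
    margin_color: Tuple[int, int, int] = GREY
    marker_color: Tuple[int, int, int] = WHITE
    marker_width_px: int = 1
    pressure_min: float = COLOR_STOPS[0][0]
    pressure_max: float = COLOR_STOPS[-1][0]

    @property
    def plot_width(self) -> int:
        return self.image_width - self.left_margin

    @property
    def plot_height(self) -> int:
        return self.image_height - self.top_margin - self.bottom_margin

    def time_to_x(self, t: float, duration: float) -> int:
        """Map a time to an x column in full-image coordinates."""
        x = self.left_margin + int(round(t / duration * self.plot_width))
        return min(x, self.image_width - 1)


@dataclass
class TopographyImage:
    """Rendered RGB raster plus geometry and (optional) ground truth.

    Pixel coordinates are 0-based with the origin at the top-left; y grows
    downward.  ``marker_x`` is the drawn marker column in full-image
    coordinates.
    """

    pixels: np.ndarray  # uint8 [H, W, 3]
    spec: RenderSpec
    truth: Optional[SwallowTruth] = None
    marker_x: Optional[int] = None


def pressure_to_rgb(pressures: np.ndarray, spec: Optional[RenderSpec] = None) -> np.ndarray:
    """Apply the jet-like color scale to an array of pressures (mmHg)."""
    p = np.clip(np.asarray(pressures, dtype=float), COLOR_STOPS[0][0], COLOR_STOPS[-1][0])
    xs = np.array([s[0] for s in COLOR_STOPS])
    out = np.empty(p.shape + (3,), dtype=np.uint8)
    for c in range(3):
        ys = np.array([s[1][c] for s in COLOR_STOPS], dtype=float)
        out[..., c] = np.rint(np.interp(p, xs, ys)).astype(np.uint8)
    return out


def sensor_row_range(
    spec: RenderSpec, n_sensors: int, sensor_lo: int, sensor_hi: int
) -> Tuple[int, int]:
    """Inclusive plot-area row interval covered by sensors [lo, hi].

    Rows are in plot-area coordinates (0 = first row below the top margin),
    i.e. the coordinates of the margin-stripped image.
    """
    h = spec.plot_height
    rows = np.arange(h) * n_sensors // h
    hits = np.nonzero((rows >= sensor_lo) & (rows <= sensor_hi))[0]
    return int(hits[0]), int(hits[-1])


def render(
    recording: PressureRecording,
    spec: Optional[RenderSpec] = None,
    truth: Optional[SwallowTruth] = None,
) -> TopographyImage:
    """Render a recording as the 60-s screen-capture raster.

    Nearest-neighbour resampling keeps the sensor bands crisp; the marker
    line is drawn without antialiasing so the white-pixel column histogram
    has a unique maximum at the marker.
    """
    spec = spec or RenderSpec()
    if spec.plot_width <= 0 or spec.plot_height <= 0:
        raise ValueError("render spec leaves no plot area")

    P = recording.pressures
    h, w = spec.plot_height, spec.plot_width
    row_sensor = np.arange(h) * recording.n_sensors // h
    col_sample = np.arange(w) * recording.n_samples // w
    field = P[np.ix_(row_sensor, col_sample)]
    plot = pressure_to_rgb(field, spec)

    marker_x = None
    for t in recording.swallow_marker_times:
        x_full = spec.time_to_x(t, recording.duration)
        x_plot = x_full - spec.left_margin
        x_hi = min(x_plot + spec.marker_width_px, w)
        plot[:, x_plot:x_hi] = spec.marker_color
        marker_x = x_full

    pixels = np.empty((spec.image_height, spec.image_width, 3), dtype=np.uint8)
    pixels[:] = spec.margin_color
    pixels[spec.top_margin : spec.top_margin + h, spec.left_margin :] = plot
    return TopographyImage(pixels=pixels, spec=spec, truth=truth, marker_x=marker_x)


def save_png(image: TopographyImage, path: str | Path) -> None:
    """Write the raster as an 8-bit RGB PNG with a JSON truth sidecar."""
    import json

    path = Path(path)
    Image.fromarray(image.pixels, mode="RGB").save(path, format="PNG")
    if image.truth is not None:
        sidecar = {
            "marker_time": image.truth.marker_time,
            "egj_sensor_range": list(image.truth.egj_sensor_range),
            "true_irp": image.truth.true_irp,
            "irp_class": image.truth.irp_class,
            "positioning": image.truth.positioning,
            "marker_x": image.marker_x,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB PNG back as a [H, W, 3] uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)
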