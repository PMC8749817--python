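"""Integrated relaxation pressure (IRP) computation.

The IRP summarizes how well the lower esophageal sphincter (LES) opens
during a swallow: it is the mean of the lowest 4 s of esophago-gastric
junction (EGJ) pressure — contiguous or not — inside the 10-s window that
follows swallow onset.  The EGJ pressure at each instant is taken as the
maximum across the EGJ sensor range (the "e-sleeve" convention, emulating a
sleeve sensor that reports the tightest point of the sphincter).

Because the selected seconds need not be contiguous, the computation
reduces to order statistics: the mean of the k = round(4 * fs) smallest
e-sleeve samples in the window.  A value above the cut-off (28 mmHg for the
Unisensor probe convention used here) is classed "high"; the cut-off is an
*upper normal limit*, so equality is classed "normal".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Tuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .sim_pressure import PressureRecording

#: Upper normal limit of IRP in mmHg.
DEFAULT_CUTOFF = 28.0
#: Length of the post-swallow analysis window, seconds.
IRP_WINDOW_S = 10.0
#: Total duration of the selected (lowest-pressure) samples, seconds.
IRP_SELECTED_S = 4.0

NORMAL = "normal"
HIGH = "high"


@dataclass(frozen=True)
class IrpResult:
    """Outcome of an IRP measurement on one swallow."""

    irp_value: float
    window_start: float
    window_duration: float
    selected_seconds: float
    irp_class: str
    cutoff: float

    def to_dict(self) -> dict:
        return {
            "irp_value": self.irp_value,
            "window_start": self.window_start,
            "window_duration": self.window_duration,
            "selected_seconds": self.selected_seconds,
            "irp_class": self.irp_class,
            "cutoff": self.cutoff,
        }


def _validate_egj_range(egj_range: Tuple[int, int], n_sensors: int) -> Tuple[int, int]:
    lo, hi = int(egj_range[0]), int(egj_range[1])
    if lo > hi:
        raise ValueError(f"empty EGJ sensor range {egj_range!r}")
    if lo < 0 or hi >= n_sensors:
        raise ValueError(
            f"EGJ range {egj_range!r} outside sensor bounds [0, {n_sensors})"
        )
    return lo, hi


def esleeve_trace(recording: "PressureRecording", egj_range: Tuple[int, int]) -> np.ndarray:
    """Per-sample maximum pressure across the EGJ sensors (inclusive range).

    Returns one value per time sample, in mmHg.
    """
    pressures = np.asarray(recording.pressures, dtype=float)
    lo, hi = _validate_egj_range(egj_range, pressures.shape[0])
    return pressures[lo : hi + 1].max(axis=0)


def compute_irp(
    recording: "PressureRecording",
    marker_time: float,
    egj_range: Tuple[int, int],
    cutoff: float = DEFAULT_CUTOFF,
) -> IrpResult:
    """Measure the IRP in the 10 s after a swallow marker.

    The window is anchored at ``marker_time`` (the white-line swallow mark).
    With sampling rate fs, the result is the mean of the k = round(4 * fs)
    smallest e-sleeve samples among the round(10 * fs) window samples.
    """
    fs = float(recording.sampling_rate)
    n_samples = np.asarray(recording.pressures).shape[1]
    i0 = int(round(marker_time * fs))
    n_win = int(round(IRP_WINDOW_S * fs))
    if marker_time < 0 or i0 + n_win > n_samples:
        raise ValueError(
            f"IRP window [{marker_time}, {marker_time + IRP_WINDOW_S}] s "
            f"exceeds the recording ({n_samples / fs} s)"
        )
    trace = esleeve_trace(recording, egj_range)[i0 : i0 + n_win]
    k = int(round(IRP_SELECTED_S * fs))
    k = min(k, trace.size)
    lowest = np.partition(trace, k - 1)[:k]
    irp_value = float(lowest.mean())
    return IrpResult(
        irp_value=irp_value,
        window_start=float(marker_time),
        window_duration=IRP_WINDOW_S,
        selected_seconds=IRP_SELECTED_S,
        irp_class=classify_irp(irp_value, cutoff),
        cutoff=float(cutoff),
    )


def classify_irp(irp_value: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Class label for an IRP value: ``high`` iff strictly above the cut-off.

    The cut-off is the *upper normal limit*, so a value equal to it is
    still normal.
    """
    if not np.isfinite(irp_value) or not np.isfinite(cutoff):
        raise ValueError("irp_value and cutoff must be finite")
    return HIGH if irp_value > cutoff else NORMAL
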