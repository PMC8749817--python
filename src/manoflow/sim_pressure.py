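"""Synthetic high-resolution manometry (HRM) pressure recordings.

Generates 36-sensor pressure matrices with known ground truth for every
downstream stage: a lower-esophageal-sphincter (LES) high-pressure band
just above a low-pressure gastric band, a propagating peristaltic ridge
after the wet swallow, swallow-induced LES relaxation (deep for a normal
integrated relaxation pressure, shallow/absent for a high one), and two
probe-positioning-failure patterns (a mirrored duplicate pressure band from
a folded/coiled catheter; a missing LES band).

Four scenarios are supported:

``normal_irp``
    Deep raised-cosine LES relaxation after the marker; IRP well below the
    28 mmHg cut-off.
``high_irp``
    Relaxation essentially absent (nadir near resting pressure); IRP stays
    above the cut-off.
``failure_mirror``
    Normal physiology reflected about the distal end of the EGJ so a
    duplicate high-pressure band appears below it, as produced by a folded
    catheter.
``failure_no_les``
    No sustained high-pressure band in the distal channels (catheter not
    across the sphincter).

The per-swallow ground truth (``SwallowTruth``) stores the marker time,
the EGJ sensor range, the true IRP — *defined* as the IRP engine's output
on the generated recording — and the class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import irp_engine

# ---------------------------------------------------------------- geometry
N_SENSORS = 36
SAMPLING_RATE = 10.0  # Hz; chosen so the 10-s IRP window holds 100 samples
SENSOR_SPACING = 1.0  # cm
DURATION = 60.0  # s of recording per rendered screen image

#: Inclusive sensor-index interval of the esophago-gastric junction (EGJ).
EGJ_RANGE: Tuple[int, int] = (30, 32)
#: Sensors in the stomach (the protocol requires at least 3).
GASTRIC_RANGE: Tuple[int, int] = (33, 35)
#: Upper esophageal sphincter band.
UES_RANGE: Tuple[int, int] = (0, 1)
#: Esophageal body (peristaltic) sensors.
BODY_RANGE: Tuple[int, int] = (2, 29)

GASTRIC_BASELINE = 5.0  # mmHg, the manometric reference
BODY_BASELINE = 10.0  # mmHg
UES_PRESSURE = 40.0  # mmHg resting band at the top of the plot
PRESSURE_FLOOR = -20.0
PRESSURE_CEIL = 300.0

SCENARIOS = ("normal_irp", "high_irp", "failure_mirror", "failure_no_les")
CORRECT = "correct"
FAILURE = "failure"


class ConfigurationError(ValueError):
    """Raised for invalid scenario names or inconsistent parameters."""


@dataclass(frozen=True)
class SimulationParams:
    """Physiological and noise parameters for one simulated swallow."""

    scenario: str
    les_resting_pressure: float = 30.0
    relaxation_nadir: float = 5.0
    relaxation_duration: float = 8.0  # s
    wave_speed: float = 3.0  # cm/s, proximal-to-distal
    wave_amplitude: float = 80.0  # mmHg peak of the peristaltic ridge
    noise_sd: float = 1.5  # mmHg additive Gaussian noise
    rng_seed: int = 0
    marker_time: Optional[float] = None  # s; default jitters near mid-recording

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.relaxation_nadir > self.les_resting_pressure:
            raise ConfigurationError("relaxation_nadir must not exceed resting pressure")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


def default_params(scenario: str, rng_seed: int = 0) -> SimulationParams:
    """Study-condition defaults per scenario.

    normal_irp relaxes deeply (30 -> 5 mmHg); high_irp barely relaxes
    (35 -> 33 mmHg). The failure scenarios reuse the normal physiology,
    altered only in catheter geometry.
    """
    if scenario in ("high_irp",):
        return SimulationParams(
            scenario=scenario,
            les_resting_pressure=35.0,
            relaxation_nadir=33.0,
            rng_seed=rng_seed,
        )
    return SimulationParams(scenario=scenario, rng_seed=rng_seed)


@dataclass(frozen=True)
class SwallowTruth:
    """Simulator ground truth for one wet swallow."""

    marker_time: float
    egj_sensor_range: Tuple[int, int]
    true_irp: float
    irp_class: str
    positioning: str


@dataclass
class PressureRecording:
    """A sensor-by-time pressure matrix with acquisition metadata."""

    pressures: np.ndarray  # [n_sensors, n_samples], mmHg
    sampling_rate: float = SAMPLING_RATE
    sensor_spacing: float = SENSOR_SPACING
    duration: float = DURATION
    swallow_marker_times: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.pressures.ndim != 2:
            raise ValueError("pressures must be a 2-D sensor x time matrix")
        expected = int(round(self.duration * self.sampling_rate))
        if self.pressures.shape[1] != expected:
            raise ValueError(
                f"expected {expected} samples for {self.duration} s at "
                f"{self.sampling_rate} Hz, got {self.pressures.shape[1]}"
            )
        if not np.all(np.isfinite(self.pressures)):
            raise ValueError("pressures must be finite")
        for t in self.swallow_marker_times:
            if not (0 <= t < self.duration):
                raise ValueError(f"marker time {t} outside [0, {self.duration})")

    @property
    def n_sensors(self) -> int:
        return self.pressures.shape[0]

    @property
    def n_samples(self) -> int:
        return self.pressures.shape[1]

    def save(self, path: str | Path) -> None:
        """Write to ``.npz`` (flat binary) or ``.csv`` (matrix with header)."""
        path = Path(path)
        if path.suffix == ".npz":
            np.savez(
                path,
                pressures=self.pressures,
                sampling_rate=self.sampling_rate,
                sensor_spacing=self.sensor_spacing,
                duration=self.duration,
                swallow_marker_times=np.asarray(self.swallow_marker_times),
            )
        elif path.suffix == ".csv":
            with open(path, "w") as fh:
                fh.write(f"# sampling_rate={self.sampling_rate}\n")
                fh.write(f"# sensor_spacing={self.sensor_spacing}\n")
                fh.write(f"# duration={self.duration}\n")
                markers = ",".join(str(t) for t in self.swallow_marker_times)
                fh.write(f"# swallow_marker_times={markers}\n")
                np.savetxt(fh, self.pressures, delimiter=",")
        else:
            raise ValueError(f"unsupported recording format {path.suffix!r}")

    @classmethod
    def load(cls, path: str | Path) -> "PressureRecording":
        path = Path(path)
        if path.suffix == ".npz":
            with np.load(path) as data:
                return cls(
                    pressures=data["pressures"],
                    sampling_rate=float(data["sampling_rate"]),
                    sensor_spacing=float(data["sensor_spacing"]),
                    duration=float(data["duration"]),
                    swallow_marker_times=list(data["swallow_marker_times"]),
                )
        if path.suffix == ".csv":
            meta = {}
            with open(path) as fh:
                lines = fh.readlines()
            for line in lines:
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    meta[key.strip()] = value.strip()
            pressures = np.loadtxt(
                [l for l in lines if not l.startswith("#")], delimiter=","
            )
            markers = [
                float(t) for t in meta.get("swallow_marker_times", "").split(",") if t
            ]
            return cls(
                pressures=pressures,
                sampling_rate=float(meta.get("sampling_rate", SAMPLING_RATE)),
                sensor_spacing=float(meta.get("sensor_spacing", SENSOR_SPACING)),
                duration=float(meta.get("duration", DURATION)),
                swallow_marker_times=markers,
            )
        raise ValueError(f"unsupported recording format {path.suffix!r}")


# ------------------------------------------------------------- simulation
def _raised_cosine_dip(t: np.ndarray, start: float, duration: float, depth: float) -> np.ndarray:
    """Smooth relaxation dip: 0 outside [start, start+duration], peak `depth`."""
    phase = (t - start) / duration
    active = (phase >= 0) & (phase <= 1)
    dip = np.zeros_like(t)
    dip[active] = depth * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[active]))
    return dip


def simulate_recording(params: SimulationParams) -> Tuple[PressureRecording, SwallowTruth]:
    """Generate one 60-s recording containing a single wet swallow.

    Identical parameters (including the seed) give a bit-identical matrix.
    The returned truth's ``true_irp`` is *defined* as ``compute_irp`` applied
    to the generated recording over the true EGJ range.
    """
    rng = np.random.default_rng(params.rng_seed)
    n_samples = int(round(DURATION * SAMPLING_RATE))
    t = np.arange(n_samples) / SAMPLING_RATE

    marker_time = params.marker_time
    if marker_time is None:
        # wet-swallow mark close to the middle of the 60-s image
        marker_time = float(rng.uniform(27.0, 33.0))

    P = np.zeros((N_SENSORS, n_samples))
    P[UES_RANGE[0] : UES_RANGE[1] + 1] = UES_PRESSURE
    P[BODY_RANGE[0] : BODY_RANGE[1] + 1] = BODY_BASELINE
    P[GASTRIC_RANGE[0] : GASTRIC_RANGE[1] + 1] = GASTRIC_BASELINE

    if params.scenario == "failure_no_les":
        # catheter not across the sphincter: distal channels look like body
        P[EGJ_RANGE[0] : EGJ_RANGE[1] + 1] = BODY_BASELINE
    else:
        P[EGJ_RANGE[0] : EGJ_RANGE[1] + 1] = params.les_resting_pressure
        depth = params.les_resting_pressure - params.relaxation_nadir
        dip = _raised_cosine_dip(t, marker_time, params.relaxation_duration, depth)
        P[EGJ_RANGE[0] : EGJ_RANGE[1] + 1] -= dip[None, :]

    # peristaltic ridge: a Gaussian pressure wave sweeping the esophageal
    # body from proximal to distal at wave_speed
    if params.wave_amplitude > 0:
        body = np.arange(BODY_RANGE[0], BODY_RANGE[1] + 1)
        latency = 0.5  # s between the mark and the ridge entering the body
        arrival = (
            marker_time
            + latency
            + (body - BODY_RANGE[0]) * SENSOR_SPACING / params.wave_speed
        )
        sigma_t = 1.5  # s ridge width
        ridge = params.wave_amplitude * np.exp(
            -0.5 * ((t[None, :] - arrival[:, None]) / sigma_t) ** 2
        )
        P[BODY_RANGE[0] : BODY_RANGE[1] + 1] += ridge

    if params.scenario == "failure_mirror":
        # folded catheter: bands reflected about the distal EGJ edge, so a
        # duplicate high-pressure band appears below the EGJ
        lo, hi = EGJ_RANGE
        n_mirror = GASTRIC_RANGE[1] - GASTRIC_RANGE[0] + 1
        src = np.arange(hi, hi - n_mirror, -1)
        P[GASTRIC_RANGE[0] : GASTRIC_RANGE[1] + 1] = P[src]

    if params.noise_sd > 0:
        P += rng.normal(0.0, params.noise_sd, P.shape)

    # baseline channels never read below the gastric reference floor
    low_rows = slice(BODY_RANGE[0], GASTRIC_RANGE[1] + 1)
    P[low_rows] = np.maximum(P[low_rows], 0.0)
    np.clip(P, PRESSURE_FLOOR, PRESSURE_CEIL, out=P)

    recording = PressureRecording(pressures=P, swallow_marker_times=[marker_time])
    result = irp_engine.compute_irp(recording, marker_time, EGJ_RANGE)
    positioning = (
        FAILURE if params.scenario in ("failure_mirror", "failure_no_les") else CORRECT
    )
    truth = SwallowTruth(
        marker_time=marker_time,
        egj_sensor_range=EGJ_RANGE,
        true_irp=result.irp_value,
        irp_class=result.irp_class,
        positioning=positioning,
    )
    return recording, truth


MANIFEST_COLUMNS = [
    "file",
    "scenario",
    "positioning",
    "irp_class",
    "true_irp",
    "marker_time",
    "marker_x",
]


def batch_generate(
    n_per_class: int,
    scenarios: Sequence[str],
    seed: int,
    out_dir: str | Path,
    render_spec=None,
) -> pd.DataFrame:
    """Render ``n_per_class`` images per scenario and write a CSV manifest.

    Seeds for the individual draws are derived deterministically from
    ``seed``, so the same call produces byte-identical images and manifest.
    Returns the manifest as a DataFrame (also written to
    ``out_dir/manifest.csv``).
    """
    from . import topo_render  # deferred to keep module import cheap

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    for s in scenarios:
        if s not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {s!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    spec = render_spec if render_spec is not None else topo_render.RenderSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(scenarios) * n_per_class
    ) % (2**31)
    rows = []
    idx = 0
    for scenario in scenarios:
        for i in range(n_per_class):
            params = default_params(scenario, rng_seed=int(child_seeds[idx]))
            idx += 1
            recording, truth = simulate_recording(params)
            image = topo_render.render(recording, spec, truth=truth)
            fname = f"{scenario}_{i:04d}.png"
            topo_render.save_png(image, out_dir / fname)
            rows.append(
                {
                    "file": fname,
                    "scenario": scenario,
                    "positioning": truth.positioning,
                    "irp_class": truth.irp_class,
                    "true_irp": truth.true_irp,
                    "marker_time": truth.marker_time,
                    "marker_x": image.marker_x,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
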