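from pathlib import Path

import numpy as np
import pytest

from manoflow import sim_pressure, topo_render


@pytest.fixture(scope="session")
def small_batch_dir(tmp_path_factory) -> Path:
    """A small rendered batch (2 per scenario, all scenarios) with manifest."""
    out = tmp_path_factory.mktemp("batch")
    sim_pressure.batch_generate(2, list(sim_pressure.SCENARIOS), seed=11, out_dir=out)
    return out


@pytest.fixture()
def normal_recording():
    rec, truth = sim_pressure.simulate_recording(
        sim_pressure.default_params("normal_irp", rng_seed=5)
    )
    return rec, truth


@pytest.fixture()
def rendered_normal(normal_recording):
    rec, truth = normal_recording
    return topo_render.render(rec, truth=truth)


def make_recording(pressures, markers=()):
    """Wrap a raw matrix as a recording, padding metadata to defaults."""
    return sim_pressure.PressureRecording(
        pressures=np.asarray(pressures, dtype=float),
        swallow_marker_times=list(markers),
    )
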