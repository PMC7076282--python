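import numpy as np
import pytest

from neurocal import (
    TraceSet, SpikingSimParams, SOCESimParams,
    simulate_spiking, simulate_soce, fluo4_epoch_plan, soce_epoch_plan,
)
from neurocal.transients import NormalizedTrace


@pytest.fixture
def fluo4_plan():
    return fluo4_epoch_plan()


@pytest.fixture
def soce_plan():
    return soce_epoch_plan()


@pytest.fixture
def clean_spiking():
    """Noise-free, bleach-free spiking recording with truth."""
    params = SpikingSimParams(n_cells=10, noise_sd=0.0, seed=7)
    return simulate_spiking(params) + (params,)


@pytest.fixture
def clean_soce():
    """Zero-noise SOCE recording with the canonical truth constants."""
    params = SOCESimParams(n_cells=4, noise_sd=0.0, seed=3)
    return simulate_soce(params) + (params,)


def make_nt(dff: np.ndarray, dt: float = 1.0) -> NormalizedTrace:
    """Wrap a dff matrix (frames x cells) as a NormalizedTrace."""
    dff = np.atleast_2d(np.asarray(dff, dtype=float).T).T
    n_frames, n_cells = dff.shape
    return NormalizedTrace(
        times=np.arange(n_frames) * dt, norm=dff + 1.0, dff=dff,
        f0=np.ones(n_cells), cell_ids=[f"c{j}" for j in range(n_cells)],
        reference_frame=0)


@pytest.fixture
def trace_file(tmp_path):
    def _write(times, values, cell_ids=None, name="trace.tsv"):
        values = np.atleast_2d(np.asarray(values, dtype=float).T).T
        cell_ids = cell_ids or [f"roi{j}" for j in range(values.shape[1])]
        path = tmp_path / name
        lines = ["time_s\t" + "\t".join(cell_ids)]
        for t, row in zip(times, values):
            lines.append("\t".join([repr(float(t))] + [repr(float(v)) for v in row]))
        path.write_text("\n".join(lines) + "\n")
        return path
    return _write
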