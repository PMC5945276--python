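import numpy as np
import pytest

from lacoresect.config import RunConfig
from lacoresect.focus_quant import FocusMeasurement, FocusTrace
from lacoresect.pipeline import run_pipeline
from lacoresect.simulate import GenotypeRateModel, SimulationConfig


def make_trace(
    intensities,
    detected=None,
    noise_sd=1.0,
    centers=None,
    channel="GFP",
    dt=10.0,
    cell_id="cell",
    genotype="WT",
):
    """Build a FocusTrace directly from per-frame values (no imaging)."""
    intensities = np.asarray(intensities, dtype=float)
    n = len(intensities)
    if detected is None:
        detected = [True] * n
    if centers is None:
        centers = [(5.0, 10.0, 10.0)] * n
    ms = [
        FocusMeasurement(
            frame_index=i,
            channel=channel,
            center_zyx=tuple(centers[i]),
            integrated_intensity=float(intensities[i]),
            background_per_voxel=0.0,
            noise_sd=float(noise_sd),
            detected=bool(detected[i]),
        )
        for i in range(n)
    ]
    return FocusTrace(cell_id, channel, dt, ms, genotype=genotype)


@pytest.fixture
def trace_factory():
    return make_trace


@pytest.fixture(scope="session")
def small_cut_run():
    """One small rendered movie of cut cells pushed through the full pipeline."""
    cfg = RunConfig()
    cfg.simulation = SimulationConfig(
        n_cells=6,
        cut_fraction=1.0,
        n_frames=24,
        z_slices=15,
        genotype_rate_model={"WT": GenotypeRateModel(7.6, sigma_log=0.2)},
        seed=42,
    )
    return cfg, run_pipeline(cfg)


@pytest.fixture(scope="session")
def small_uncut_stack():
    """A tiny rendered movie of uncut cells (photobleaching only)."""
    from lacoresect.simulate import render_stack, simulate_events

    cfg = RunConfig()
    sim = SimulationConfig(
        n_cells=3,
        cut_fraction=0.0,
        n_frames=8,
        z_slices=11,
        genotype_rate_model={"WT": GenotypeRateModel(7.6)},
        seed=7,
    )
    events = simulate_events(sim, cfg.geometry)
    stack, truth = render_stack(events, sim, cfg.geometry)
    return cfg, stack, truth
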