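import numpy as np
import pytest

import fretscreen as fs


@pytest.fixture(scope="session")
def timebase():
    return fs.default_timebase()


@pytest.fixture(scope="session")
def small_noiseless_well():
    """A small noiseless wild-type-like well: 30 identical-amplitude cells,
    ~29% responders, 192x192 field."""
    params = fs.SimParams.wild_type(n_cells=30, field_shape=(192, 192)).noiseless()
    return fs.simulate_well(params, 11, well_id="A01"), params


@pytest.fixture(scope="session")
def noisy_well():
    """A default-noise wild-type-like well of 100 cells."""
    params = fs.SimParams.wild_type(n_cells=100, field_shape=(384, 384))
    return fs.simulate_well(params, 1, well_id="A01"), params


def archetype_cell(params: "fs.SimParams", responder: bool = True, peak_scale: float = 1.0):
    return fs.CellGroundTruth(
        cell_id=1,
        nucleus_center=(50.0, 50.0),
        nucleus_radius=params.nucleus_radius_mean,
        cytoplasm_radius=params.cytoplasm_radius_mean,
        is_responder=responder,
        peak_scale=peak_scale if responder else 0.0,
        baseline_calcium=params.baseline_calcium,
        rise_tau=params.rise_tau,
        decay_tau=params.decay_tau,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
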