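import numpy as np
import pytest

import ephysbench as eb


@pytest.fixture(scope="session")
def small_scenario_config():
    """A miniature single-block scenario that runs in well under a second."""
    return {
        "name": "mini",
        "duration_s": 2.0,
        "sampling_rate_hz": 20000.0,
        "refractory_s": 0.002,
        "probe": {"preset": "tetrode"},
        "tissue": {
            "kind": "single",
            "volume_mm3": 0.05,
            "density_per_mm3": 40000.0,
            "active_fraction": 0.5,
            "pyramidal_fraction": 0.8,
            "rate_model": {"kind": "uniform_bounds", "min_rate_hz": 0.5, "max_rate_hz": 12.0},
        },
        "interneuron_rate_factor": 5.0,
        "attenuation": {
            "reference_distance_um": 50.0,
            "reference_amplitude_uv": 50.0,
            "minimum_distance_um": 10.0,
            "noise_radius_um": 100.0,
        },
        "background_radius_um": 200.0,
        "templates": {"n": 6, "pyramidal_mix": 0.8},
        "lfp": {"condition": "awake", "rms_uv": 100.0},
        "artefacts": {"classes": ["mechanical_shock"], "rate_per_s": 2.0},
    }


@pytest.fixture(scope="session")
def small_dataset(small_scenario_config):
    return eb.run_scenario(small_scenario_config, seed=42)


@pytest.fixture(scope="session")
def awake_dataset():
    """One full awake benchmark (10 s, 16 channels), shared across tests."""
    return eb.run_scenario("awake", seed=1)


def single_unit_population(position):
    """One-unit population helper for rendering tests."""
    return eb.NeuronPopulation(
        positions=np.asarray([position], dtype=float),
        cell_type=np.asarray(["pyramidal"]),
        rate=np.asarray([5.0]),
        active=np.asarray([True]),
        layer_id=np.asarray([0], dtype=np.int32),
    )
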