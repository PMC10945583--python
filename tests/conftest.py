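import numpy as np
import pytest

from thcdosim import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def noiseless_config():
    """Generator config with every dispersion parameter zeroed, so the
    analyses must reproduce the generator parameters exactly."""
    base = SimulationConfig()
    return SimulationConfig.from_dict({
        **base.to_dict(),
        "noise_sd": {k: 0.0 for k in base.noise_sd},
        "consumed_dose_cv": 0.0,
        "pk_animal_cv": 0.0,
        "consumption_profiles": {
            k: {**base.to_dict()["consumption_profiles"][k],
                "animal_rate_cv": 0.0}
            for k in base.consumption_profiles},
        "baselines": {k: (m, 0.0) for k, (m, _) in base.baselines.items()},
        "body_mass_sd": 1e-9,
    })


@pytest.fixture
def small_config():
    return SimulationConfig.from_dict({**SimulationConfig().to_dict(),
                                       "n_per_group": 4})
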