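import numpy as np
import pytest

from qapk.pk_model import reference_params
from qapk.quantitation import quantify_study
from qapk.synthetic import default_config, generate_study


@pytest.fixture(scope="session")
def deam_params():
    """Published deamidation-model parameters, unit dose."""
    return reference_params("deamidation")


@pytest.fixture(scope="session")
def man5_params():
    """Published Man5-model parameters, unit dose."""
    return reference_params("man5")


@pytest.fixture(scope="session")
def day_grid():
    """0-42 day grid dense enough for closed-form comparisons."""
    return np.linspace(0.0, 42.0, 85)


@pytest.fixture(scope="session")
def noise_free_study():
    """Default study conditions with the noise switched off."""
    return generate_study(default_config(seed=11, noise_cv=0.0))


@pytest.fixture(scope="session")
def noise_free_quant(noise_free_study):
    cfg = noise_free_study.config
    reporters = {a.name: f"MODPEP_{a.name}" for a in cfg.attribute_specs}
    return quantify_study(
        noise_free_study.peak_table,
        reporters,
        calibrant_amount=cfg.calibrant_amount,
        serum_volume=cfg.serum_volume,
    )
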