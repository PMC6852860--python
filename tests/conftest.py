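from datetime import date

import pytest
from hypothesis import settings

from fattenassoc.synthetic_herd import (
    GainModelSpec,
    HerdConfig,
    IntakeModelSpec,
    MarkerSpec,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def noise_free_config() -> HerdConfig:
    """Deterministic linear growth: 1 kg/day from 80 kg, DMI = 0.1 * W^0.75."""
    return HerdConfig(
        n_animals=1,
        markers=(MarkerSpec(name="M1", alleles=("A", "B"), allele_freq=0.5),),
        gain_model=GainModelSpec(
            baseline_adwg=1.0,
            season_effects={},
            animal_sd=0.0,
            residual_sd=0.0,
            initial_weight_mean=80.0,
            initial_weight_sd=0.0,
        ),
        intake_model=IntakeModelSpec(intake_coefficient=0.1, noise_sd=0.0),
        start_date_range=(date(2016, 1, 1), date(2016, 1, 1)),
        age_at_start_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_herd():
    """A small but fully featured simulated cohort, shared across tests."""
    from fattenassoc.synthetic_herd import generate_herd

    return generate_herd(HerdConfig(n_animals=60, seed=123))
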