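import numpy as np
import pytest
from hypothesis import settings

from nafldsim import (DamageRepairParams, EnsembleSpec, HitEvent,
                      LUMetabolicParams, SinusoidGeometry, stable_eta)
from nafldsim.ensemble import sample_cohort, simulate_progression_cohort

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_metabolic():
    return LUMetabolicParams()


@pytest.fixture(scope="session")
def ref_geometry():
    return SinusoidGeometry()


@pytest.fixture(scope="session")
def ref_damage():
    return DamageRepairParams()


@pytest.fixture(scope="session")
def healthy_eta(ref_damage):
    return stable_eta(ref_damage.k_d, ref_damage)


@pytest.fixture(scope="session")
def het_cohort_results():
    """100 heterogeneous 100-LU livers through the standard 30-year challenge."""
    livers = sample_cohort(100, EnsembleSpec(n_lu=100, cv=0.2, seed=42))
    return simulate_progression_cohort(livers, horizon_years=35.0,
                                       save_every_days=30.0)


@pytest.fixture(scope="session")
def hom_cohort_results():
    """100 functionally homogeneous livers (one draw per liver) through the challenge."""
    livers = sample_cohort(100, EnsembleSpec(n_lu=100, cv=0.2, seed=43,
                                             homogeneous=True))
    return simulate_progression_cohort(livers, horizon_years=35.0,
                                       save_every_days=90.0)


@pytest.fixture(scope="session")
def standard_hits():
    return tuple(HitEvent.from_years(t) for t in (5.0, 8.0, 11.0))
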