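import pytest

from indelsig.model import ScanParams
from indelsig.simulate import (
    CladeSpec,
    make_plan,
    plant_csis,
    simulate_proteomes,
)


@pytest.fixture(scope="session")
def default_params():
    return ScanParams()


@pytest.fixture(scope="session")
def small_cohort():
    """10 genomes in 3 clades, 20 families, no planted indels."""
    spec = CladeSpec((("A", 4), ("B", 3), ("C", 3)),
                     within_rate=0.03, between_rate=0.12)
    return simulate_proteomes(spec, 20, (150, 400), seed=11)


@pytest.fixture(scope="session")
def planted_cohort(small_cohort, default_params):
    """The small cohort with 6 planted CSIs (2 with a missing homologue)."""
    plan = make_plan(small_cohort, 6, seed=12, params=default_params,
                     n_missing=2)
    mutated, manifest = plant_csis(small_cohort, plan, default_params, seed=13)
    return mutated, manifest
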