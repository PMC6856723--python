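import numpy as np
import pytest

from sulfurflux.community_builder import TOY_EUROPEAN_DIET, build_community
from sulfurflux.synthetic_data import (
    CohortSpec,
    PanelSpec,
    generate_abundance_profiles,
    generate_longitudinal_metabolome,
    generate_strain_panel,
)


@pytest.fixture(scope="session")
def panel():
    return generate_strain_panel(PanelSpec(3, True, True, seed=1))


@pytest.fixture(scope="session")
def profiles_and_groups(panel):
    return generate_abundance_profiles(panel, 10, 10, keystone_shift=0.7, seed=2)


@pytest.fixture(scope="session")
def community(panel, profiles_and_groups):
    profiles, _ = profiles_and_groups
    return build_community(panel, profiles[0], TOY_EUROPEAN_DIET)


@pytest.fixture(scope="session")
def cohort_table():
    spec = CohortSpec(
        trajectory_assignments={
            "homoserine": "type1",
            "cystathionine": "type2",
            "methionine": "type3",
            "serine": "null",
        },
        interaction_effects=[("sm1", "sm2", -0.53)],
        include_levodopa=True,
        seed=11,
    )
    return generate_longitudinal_metabolome(spec)
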