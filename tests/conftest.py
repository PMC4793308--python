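import numpy as np
import pytest
from hypothesis import settings

import howlernet as hn

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table3():
    return hn.load_fixture("table3_items")


@pytest.fixture(scope="session")
def study_scenario():
    """One study-scale synthetic scenario shared across tests."""
    return hn.generate_scenario(hn.paper_like_config(seed=42, nu=0.8))


@pytest.fixture(scope="session")
def continuous_matrix(study_scenario):
    return hn.build_interaction_matrix(
        study_scenario.records,
        "continuous",
        "count",
        study_scenario.individuals_in("continuous"),
    )


@pytest.fixture
def toy_records():
    """Two individuals, three feeding bouts over two plants."""
    mk = lambda i, ind, sp, item, dur: hn.ObservationRecord(
        record_id=f"r{i}",
        habitat=hn.Habitat.continuous,
        site_id="s1",
        individual_id=ind,
        sex=hn.Sex.F,
        age_class=hn.AgeClass.adult,
        plant_species=sp,
        item=hn.Item(item),
        duration=dur,
    )
    return [
        mk(1, "ind_a", "Plant_A", "MF", 5.0),
        mk(2, "ind_a", "Plant_A", "IL", 2.5),
        mk(3, "ind_b", "Plant_B", "IL", 1.0),
    ]


def random_binary(rng, shape, fill=0.5):
    """Random binary matrix with no all-empty guarantee."""
    return (rng.random(shape) < fill).astype(int)
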