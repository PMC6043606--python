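import numpy as np
import pytest

import clonescan as cs
from clonescan.models import ClonalModel
from clonescan.synthetic import realize_panel


@pytest.fixture(scope="session")
def desk_ref():
    return cs.ReferenceGenome.desk_default(4, 100_000)


@pytest.fixture(scope="session")
def population(desk_ref):
    return cs.PopulationModel(snp_density=0.005, sfs_mode="uniform", seed=11)


@pytest.fixture(scope="session")
def panel(desk_ref, population):
    return realize_panel(desk_ref, population)


@pytest.fixture(scope="session")
def sexual_pair(desk_ref, population, panel):
    a = cs.simulate_sexual_isolate(desk_ref, population, 101, "sexA", panel)
    b = cs.simulate_sexual_isolate(desk_ref, population, 102, "sexB", panel)
    return a, b


@pytest.fixture(scope="session")
def clonal_family(desk_ref, population, panel):
    """Five clones from one inbred founder with a shared LoH block and
    sparse private mutations (tens per isolate)."""
    model = ClonalModel(
        founder_seed=7,
        n_isolates=5,
        years_since_divergence=(20, 40, 60, 80, 100),
        mu=2e-9,
        division_interval_days=2.0,
        loh_blocks=(("chr1", 20_000, 60_000), ("chr3", 10_000, 40_000)),
    )
    clones, founder = cs.simulate_clonal_isolates(
        desk_ref, population, model, panel=panel, return_founder=True
    )
    return clones, founder, model
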