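import numpy as np
import pytest

import usvkit as uk
from usvkit.multivariate import aggregate_by_individual_type


@pytest.fixture(scope="session")
def small_colony():
    """Ten males per group, deterministic."""
    return uk.build_default_colony(seed=7, n_per_group=10)


@pytest.fixture(scope="session")
def study_records():
    """Individual x type mean records for one study-composition colony."""
    colony = uk.build_study_colony(seed=1)
    table = uk.emit_feature_table(colony, cap=100)
    return aggregate_by_individual_type(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
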