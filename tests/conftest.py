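import warnings

import numpy as np
import pytest

from hdpanel import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 2x2 cohort (27 features, published effect sizes), seeded."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def null_cohort():
    """Same design with every group effect zeroed (pure noise)."""
    import dataclasses

    from hdpanel import default_panel

    feats = [
        dataclasses.replace(f, d_genotype=0.0, d_treatment=0.0, d_wt_treatment=0.0)
        for f in default_panel()
    ]
    sizes = {g: 13 for g in ("WT-Veh", "WT-C31", "R6/2-Veh", "R6/2-C31")}
    return generate_cohort(CohortConfig(group_sizes=sizes, features=feats, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
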