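import numpy as np
import pytest

from metaboscore.simulate import CohortParams, SlideParams, generate_cohort, generate_slide


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortParams(n_patients=400, seed=11))


@pytest.fixture(scope="session")
def plain_slide():
    """Disc tumor, margin effect 2, no macrophages, no artefacts."""
    return generate_slide(SlideParams(seed=3, margin_effect=2.0, dab_fraction_center=0.2))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
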