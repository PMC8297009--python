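import numpy as np
import pytest

import pfactorlab as pf


@pytest.fixture(scope="session")
def caspi_params():
    return pf.generating_parameters("caspi", "revised_bifactor")


@pytest.fixture(scope="session")
def simdata_params():
    return pf.generating_parameters("simdata", "revised_bifactor")


@pytest.fixture(scope="session")
def spec_c():
    return pf.build_model("C_revised_bifactor")


@pytest.fixture(scope="session")
def small_population():
    """A 20,000-subject population under the default study conditions,
    shared across tests that only need moderate sampling precision."""
    return pf.generate_population(pf.SimulationConfig(n_subjects=20_000, seed=11))


@pytest.fixture(scope="session")
def small_population_fit(small_population, spec_c):
    moments = pf.SampleMoments.from_data(small_population.symptoms.to_numpy())
    return pf.fit_ml(moments, spec_c)


def toy_single_factor_spec(p: int) -> pf.ModelSpec:
    """Single-factor model over p generic indicators."""
    return pf.ModelSpec(
        model_id="D_single",
        indicators=tuple(f"x{i}" for i in range(p)),
        factor_labels=("g",),
        loading_pattern=np.ones((p, 1), dtype=bool),
        free_factor_correlations=frozenset(),
        fixed_orthogonal=frozenset(),
    )
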