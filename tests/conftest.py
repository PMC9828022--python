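import numpy as np
import pytest

from serialsfs import (
    MultiSFS,
    ParameterVector,
    SampleSpec,
    SimulationConfig,
    model6_reference,
)
from serialsfs.sfs import CohortInfo


@pytest.fixture(scope="session")
def small_design() -> SampleSpec:
    """Three serially sampled cohorts, small enough for fast simulation."""
    return SampleSpec(("c94", "c97", "c08"), (4, 6, 8), (7.0, 5.5, 0.0))


@pytest.fixture(scope="session")
def single_cohort() -> SampleSpec:
    return SampleSpec(("now",), (4,), (0.0,))


@pytest.fixture(scope="session")
def constant_model() -> ParameterVector:
    return ParameterVector(1, {"NANC": 2000.0})


@pytest.fixture(scope="session")
def reference_model6() -> ParameterVector:
    return model6_reference()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def random_sfs(rng, small_design) -> MultiSFS:
    """A random observed (unfolded) spectrum over the small design."""
    dims = small_design.dims
    counts = rng.integers(0, 5, size=dims)
    cohorts = tuple(
        CohortInfo(l, n, t)
        for l, n, t in zip(
            small_design.labels, small_design.n_haploid, small_design.times
        )
    )
    return MultiSFS(counts, cohorts, folded=False, kind="counts")


@pytest.fixture(scope="session")
def fast_cfg() -> SimulationConfig:
    return SimulationConfig(n_sims=2000, seed=7)
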