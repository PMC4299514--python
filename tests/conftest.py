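import pytest

from warburgflux.synthetic import (
    build_micro3,
    build_parallel_path,
    build_toy_core,
    build_warburg_mini,
    generate_cohort,
)

# sampler settings used throughout the unit tests: small but well mixed
FAST_SAMPLER = dict(n=300, burn_in=300, thinning=20)


@pytest.fixture(scope="session")
def warburg_mini():
    return build_warburg_mini()


@pytest.fixture(scope="session")
def micro3():
    return build_micro3()


@pytest.fixture(scope="session")
def parallel_path():
    return build_parallel_path()


@pytest.fixture(scope="session")
def toy_core():
    return build_toy_core()


@pytest.fixture(scope="session")
def cancer_cohort():
    return generate_cohort(n_lines=10, seed=11, mode="cancer")


@pytest.fixture(scope="session")
def normal_cohort():
    return generate_cohort(n_lines=6, seed=12, mode="normal")


@pytest.fixture(scope="session")
def cohort_models(cancer_cohort, normal_cohort):
    from warburgflux.pipeline import build_cohort_models

    return build_cohort_models([cancer_cohort, normal_cohort])
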