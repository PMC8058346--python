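import pytest

from thermolump import (
    extract_reduced_system,
    make_toy_network,
    make_synthetic_gem,
    partition_groups,
    split_reversible,
)


@pytest.fixture(scope="session")
def toy():
    return make_toy_network()


@pytest.fixture(scope="session")
def toy_rs(toy):
    """(split model, reduced system, groups) of the toy network."""
    split = split_reversible(toy.model)
    rs = extract_reduced_system(split, toy.thermo, include_transport=True)
    return split, rs, partition_groups(rs)


@pytest.fixture(scope="session")
def small_gem():
    return make_synthetic_gem(
        n_metabolites=15, n_noise_reactions=12, missing_fraction=0.25, seed=11
    )


@pytest.fixture(scope="session")
def annotated_gem():
    """A synthetic model in which every metabolite has a formation energy."""
    return make_synthetic_gem(
        n_metabolites=12, n_noise_reactions=10, missing_fraction=0.0, seed=7
    )
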