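"""Shared fixtures: the planted benchmarks, generated once per session."""

import pytest

from pepfam.synthdata import (FamilySpec, generate_expression, generate_family,
                              generate_genomes, generate_rk_family)


@pytest.fixture(scope="session")
def family_spec():
    return FamilySpec()


@pytest.fixture(scope="session")
def family(family_spec):
    return generate_family(family_spec)


@pytest.fixture(scope="session")
def genome_data(family):
    return generate_genomes(family)


@pytest.fixture(scope="session")
def expression(family, genome_data):
    return generate_expression(
        genome_data.truth, [d.id for d in family.decoys],
        rng_seed=family.spec.rng_seed,
    )


@pytest.fixture(scope="session")
def rk_data():
    return generate_rk_family(n_decoys=100)
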