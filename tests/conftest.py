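import pytest

from fruits.synthetic import ToySpec, make_coupled_toy


@pytest.fixture(scope="session")
def canonical_spec() -> ToySpec:
    """One side product (stoich 0.2, C2), single-gene recycler, no export."""
    return ToySpec()


@pytest.fixture()
def canonical_toy(canonical_spec):
    return make_coupled_toy(canonical_spec)


@pytest.fixture(scope="session")
def mixed_spec() -> ToySpec:
    """Two side products: single-gene recycler and an isozyme (OR) pair."""
    return ToySpec(
        n_side_products=2,
        recycler_redundancy=("single", "or"),
        side_product_stoichiometry=(0.2, 0.3),
        carbon_counts=(2, 3),
        export_route=(False, True),
    )


@pytest.fixture()
def mixed_toy(mixed_spec):
    return make_coupled_toy(mixed_spec)
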