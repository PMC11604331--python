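import pytest

from nutriscope import FoodGroupTaxonomy, FoodRecord, ScoringScheme


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme.default()


@pytest.fixture(scope="session")
def taxonomy() -> FoodGroupTaxonomy:
    return FoodGroupTaxonomy.default()


_DEFAULTS = dict(
    ean="8712345000001",
    name="test product",
    ingredients="",
    food_group="breakfast_cereals",
    year=2018,
    energy_kj=1500.0,
    sugars_g=15.0,
    sfa_g=2.0,
    salt_g=0.5,
    protein_g=8.0,
    fibre_g=6.0,
    fvl_pct=0.0,
)


@pytest.fixture
def make_record():
    """Factory for valid, score-ready records with overridable fields."""

    def factory(**overrides) -> FoodRecord:
        payload = {**_DEFAULTS, **overrides}
        return FoodRecord(**payload)

    return factory
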