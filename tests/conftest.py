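import pytest
from hypothesis import settings

from orphanpdp import PricePoint, PricingModel

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def fig2_model() -> PricingModel:
    """The pre-specified model behind the eculizumab/bosentan example."""
    return PricingModel(f_price=10_000, pdp=130)


@pytest.fixture
def eculizumab() -> PricePoint:
    return PricePoint(drug="eculizumab", n_patients=330, price=355_740)


@pytest.fixture
def bosentan() -> PricePoint:
    return PricePoint(drug="bosentan", n_patients=990, price=10_491)
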