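import pytest

from pharmforecast import PortfolioConfig, base_case_parameters, generate


@pytest.fixture(scope="session")
def base_params():
    return base_case_parameters()


@pytest.fixture
def small_portfolio():
    """Mixed two-country portfolio exercising all lifecycle paths."""
    config = PortfolioConfig(
        seed=42,
        countries=["France", "Germany"],
        n_offpatent=8,
        n_pipeline=4,
        biologic_fraction=0.4,
    )
    return generate(config)


@pytest.fixture
def random_portfolio_50():
    """50 products across all seven countries for oracle cross-checks."""
    config = PortfolioConfig(
        seed=7,
        n_offpatent=6,
        n_pipeline=2,
        biologic_fraction=0.3,
    )
    return generate(config)[:50]
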