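import pytest

import dosagescan as ds
from dosagescan.pipeline import REFERENCE_COUNTS


@pytest.fixture(scope="session")
def reference_results():
    """Fitted analysis of the count-matched reference fixture."""
    catalog, expr, partition = ds.build_reference_count_fixture(seed=0)
    pair = ds.ExpressionPair.from_frame(expr)
    model = ds.DosageExpressionModel(
        catalog, pair, partition, region_order=list(REFERENCE_COUNTS)
    )
    return model.fit()


@pytest.fixture(scope="session")
def noiseless_full_dosage():
    """Noiseless simulation with every repeat-region gene at 2x dosage."""
    config = ds.ExpressionSimConfig(
        pi_dosage=1.0,
        pi_compensated=0.0,
        background_up_fraction=0.0,
        background_down_fraction=0.0,
        noise_log_sd=0.0,
        seed=1,
    )
    catalog, pair, truth = ds.simulate_expression_pair(config)
    return catalog, pair, truth


@pytest.fixture(scope="session")
def noiseless_default_mix():
    """Noiseless simulation at the default mixture (pi_dosage=0.346,
    background up/down fractions on)."""
    config = ds.ExpressionSimConfig(noise_log_sd=0.0, seed=5)
    catalog, pair, truth = ds.simulate_expression_pair(config)
    results = ds.DosageExpressionModel(catalog, pair, truth.partition).fit()
    return results, truth
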