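import pytest

from cobenefits import GeneratorParams, classification, generate, indicators, toy_dataset


@pytest.fixture
def toy():
    return toy_dataset()


@pytest.fixture(scope="session")
def default_draw():
    """One default-parameter synthetic draw shared across tests."""
    return generate(GeneratorParams(seed=7))


@pytest.fixture(scope="session")
def es_table(default_draw):
    """Post-filter ES dataset and its indicator table for the shared draw."""
    dataset, _ = default_draw
    classified = classification.classify_dataset(dataset)
    filtered, report = classification.filter_es(classified)
    table = indicators.indicator_table(filtered)
    return filtered, report, table
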