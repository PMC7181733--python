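import logging

import pytest

from reefmpa import biomass, regime, synthetic_data

logging.getLogger("reefmpa").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sim():
    """One study-default synthetic campaign (tables + truth metadata)."""
    tables, meta = synthetic_data.simulate_dataset(seed=11)
    return tables, meta


@pytest.fixture(scope="session")
def tables(sim):
    return sim[0]


@pytest.fixture(scope="session")
def summaries(tables):
    return biomass.summarize_reef_years(tables)


@pytest.fixture(scope="session")
def labelled(summaries, tables):
    """(sites with regimes, 2x2 design table) from classification."""
    return regime.classify_all(summaries, tables.sites, respect_override=False)
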