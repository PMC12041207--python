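import pytest

from resorb import (
    SyntheticConfig,
    incubation_records,
    leaf_records,
    pair_site_periods,
    simulate_transect,
    site_resorption_table,
)


@pytest.fixture(scope="session")
def default_transect():
    """One default synthetic transect (leaf table, incubation table, truth)."""
    return simulate_transect(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_site_tables(default_transect):
    """Paired site/replicate tables and the site resorption summary."""
    leaf_df, _, _ = default_transect
    site_df, replicate_df = pair_site_periods(leaf_records(leaf_df))
    return site_df, replicate_df, site_resorption_table(site_df)


@pytest.fixture(scope="session")
def default_incubation(default_transect):
    _, inc_df, _ = default_transect
    return incubation_records(inc_df)
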