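import pytest

from finprotect import GeneratorConfig, SurveyDesign, generate_households
from finprotect.consumption import add_aggregates


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_psu=60, households_per_psu=10, seed=11)


@pytest.fixture(scope="session")
def table(small_config):
    """600-household aggregated table."""
    return add_aggregates(generate_households(small_config))


@pytest.fixture(scope="session")
def big_table():
    """5000-household aggregated table for oracle comparisons."""
    cfg = GeneratorConfig(n_psu=250, households_per_psu=20, seed=17)
    return add_aggregates(generate_households(cfg))


@pytest.fixture(scope="session")
def table_10k():
    """10 000-household table for quintile share checks."""
    cfg = GeneratorConfig(n_psu=500, households_per_psu=20, seed=23)
    return add_aggregates(generate_households(cfg))


@pytest.fixture(scope="session")
def design():
    return SurveyDesign()


@pytest.fixture(scope="session")
def enriched_table(big_table):
    """big_table plus CHE flags, asset quintiles and impoverishment flags."""
    from finprotect import (
        CANONICAL_SPECS,
        PovertyLine,
        assign_asset_quintiles,
        che_indicator,
        impoverishment_flags,
        ipl_line,
    )

    df, _ = assign_asset_quintiles(big_table)
    for spec in CANONICAL_SPECS:
        df[spec.label] = che_indicator(df, spec)
    df["impoverished_national"] = impoverishment_flags(df, PovertyLine(2400.0, "external"))
    df["impoverished_ipl"] = impoverishment_flags(df, ipl_line())
    return df


def reconfig(config, **overrides):
    return GeneratorConfig(**{**config.model_dump(), **overrides})
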