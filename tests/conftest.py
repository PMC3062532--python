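import pytest

from diascale import (
    CountryProfile,
    GeneratorConfig,
    generate_countries,
    load_breastfeeding_rr,
    load_table1_fixture,
    load_table2_fixture,
)
from diascale.cli import BREASTFEEDING, COST_INPUTS, COVERAGE, PROFILES
from diascale.costing import CostInputs, write_cost_inputs
from diascale.fixtures import (
    write_breastfeeding_csv,
    write_coverage_csv,
    write_profiles_csv,
)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def ambitious():
    return load_table2_fixture("ambitious")


@pytest.fixture(scope="session")
def universal():
    return load_table2_fixture("universal")


@pytest.fixture(scope="session")
def bf_rr():
    return load_breastfeeding_rr()


@pytest.fixture(scope="session")
def small_bundle():
    return generate_countries(GeneratorConfig(n_countries=6, seed=11))


def make_profile(
    country_id="X",
    region="Africa",
    deaths=100_000.0,
    under5=1_000_000.0,
    shares=None,
    vitamin_a_deficient=True,
):
    """Single-country profile with constant population across years."""
    years = range(2010, 2016)
    if shares is None:
        shares = {"0mo": 0.05, "1-5mo": 0.25, "6-11mo": 0.30, "12-23mo": 0.25, "24-59mo": 0.15}
    return CountryProfile(
        country_id=country_id,
        region=region,
        total_population={y: under5 / 0.15 for y in years},
        under5_population={y: under5 for y in years},
        baseline_diarrheal_deaths=deaths,
        age_band_death_shares=shares,
        vitamin_a_deficient=vitamin_a_deficient,
    )


def write_bundle(bundle, directory):
    """Write a synthetic bundle in the CLI's input-directory layout."""
    directory.mkdir(parents=True, exist_ok=True)
    write_profiles_csv(directory / PROFILES, bundle.profiles)
    write_coverage_csv(directory / COVERAGE, bundle.coverage, bundle.regions)
    write_breastfeeding_csv(directory / BREASTFEEDING, bundle.breastfeeding)
    write_cost_inputs(directory / COST_INPUTS, CostInputs())
    return directory
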