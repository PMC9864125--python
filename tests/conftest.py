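import pytest
from hypothesis import settings

from canmp import io as cio
from canmp import simulate
from canmp.types import CorrectionConstants

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def constants():
    return CorrectionConstants()


@pytest.fixture(scope="session")
def reference_products():
    return cio.load_reference_products()


@pytest.fixture(scope="session")
def reference_concentrations():
    return cio.load_reference_concentrations()


@pytest.fixture(scope="session")
def reference_intake_table():
    return cio.load_reference_intake_table()


@pytest.fixture(scope="session")
def polymer_share_maps():
    frame = cio.load_reference_polymer_shares()

    def block(shape):
        sub = frame[frame["shape"] == shape]
        return dict(zip(sub["polymer"], sub["share_pct"]))

    return block("fiber"), block("fragment"), block("total")


@pytest.fixture(scope="session")
def small_survey():
    """One seeded synthetic survey with its blank dishes."""
    config = simulate.GeneratorConfig(seed=11)
    tables = simulate.generate_survey(config)
    blanks = simulate.generate_blanks(config)
    return config, tables, blanks
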