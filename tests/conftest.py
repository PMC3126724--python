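import pytest

from bstag.published import (
    PUBLISHED_TAG_TABLE,
    published_snp_assays,
    published_ssr_assays,
    published_tags,
)
from bstag.thermo import CALIBRATED_CONDITIONS


@pytest.fixture(scope="session")
def tags():
    """The six shipped tags, keyed by name."""
    return published_tags()


@pytest.fixture(scope="session")
def tag_list(tags):
    return list(tags.values())


@pytest.fixture(scope="session")
def tag_table():
    """(name, sequence, reported Tm) triples for the shipped set."""
    return PUBLISHED_TAG_TABLE


@pytest.fixture(scope="session")
def conditions():
    return CALIBRATED_CONDITIONS


@pytest.fixture(scope="session")
def ssr_assays():
    return published_ssr_assays()


@pytest.fixture(scope="session")
def snp_assays():
    return published_snp_assays()
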