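import pytest

from diatomlipid.species import DEFAULT_POOL, build_index, enumerate_compositions
from diatomlipid.synthetic import packaged_fixtures

ANNOTATED_CLASSES = ("PC", "PE", "PG", "PI", "MGDG", "DGDG", "SQDG")


@pytest.fixture(scope="session")
def default_index():
    """Candidate index over the default acyl pool for all scanned classes."""
    comps = []
    for cls in ANNOTATED_CLASSES:
        comps.extend(enumerate_compositions(DEFAULT_POOL, cls))
    return build_index(comps)


@pytest.fixture(scope="session")
def fixtures():
    """The packaged PL and GL fraction fixtures (zero noise, isotopes off)."""
    return packaged_fixtures(seed=1)
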