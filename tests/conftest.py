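import hypothesis
import pytest

from facetclean import fig2_fixture, table1_fixture

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=60
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture
def table1():
    """Facet + gold of the seven-typo failure-matrix fixture."""
    return table1_fixture()


@pytest.fixture
def fig2():
    """Facet + gold of the liver-fluke merge-list fixture."""
    return fig2_fixture()
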