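import pytest

from dosecurve import (
    BRAIN_ANCHORS,
    RADIMETRICS_BRAIN_BINS,
    PowerLawModel,
    fit_power_law,
)

#: Curve constants as printed in the source literature for the ICRP brain
#: anchors; used as a fixed, known model in unit tests of evaluation code.
PUBLISHED_CONSTANTS = (0.007392, 0.3298, -0.3586)


@pytest.fixture(scope="session")
def brain_anchors():
    return BRAIN_ANCHORS


@pytest.fixture(scope="session")
def brain_bins():
    return RADIMETRICS_BRAIN_BINS


@pytest.fixture(scope="session")
def published_model():
    """Power-law model with the literature-printed constants."""
    return PowerLawModel(*PUBLISHED_CONSTANTS)


@pytest.fixture(scope="session")
def brain_fit():
    """The package's own fit to the ICRP brain anchors (computed once)."""
    return fit_power_law(BRAIN_ANCHORS)
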