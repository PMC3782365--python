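import pytest

from pubsel import calibrate_default
from pubsel.curves import AcceptanceCurve, CurvePair


@pytest.fixture(scope="session")
def default_model():
    return calibrate_default()


@pytest.fixture(scope="session")
def default_curves(default_model):
    return default_model.curves


@pytest.fixture(scope="session")
def unbiased_curves(default_curves):
    """Identical positive and negative curves (no editorial bias)."""
    loc = default_curves.positive.location
    s = default_curves.positive.scale
    return CurvePair(
        positive=AcceptanceCurve(location=loc, scale=s, sign="positive"),
        negative=AcceptanceCurve(location=loc, scale=s, sign="negative"),
    )
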