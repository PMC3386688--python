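import pytest

from lifemon.synthetic_data import make_separable_fixture


@pytest.fixture(scope="session")
def separable():
    """Noise-free two-day fixture: one unique sensor set per activity."""
    return make_separable_fixture(days=2)


@pytest.fixture(scope="session")
def separable_windows(separable):
    return separable.labeled_windows(60)
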