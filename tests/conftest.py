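import pytest

from seadose import default_bundle
from seadose.datasets import load_malacca_activity, load_malacca_metals


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def survey_activity():
    return load_malacca_activity()


@pytest.fixture(scope="session")
def survey_metals():
    return load_malacca_metals()


def matches_printed(computed, printed, decimals=None, sig=None, rel_tol=0.005):
    """True when half-up rounding at the printed precision reproduces the
    printed value, or the relative difference is within ``rel_tol``."""
    from seadose.rounding import round_half_up, round_sig_figs

    if decimals is not None and round_half_up(computed, decimals) == printed:
        return True
    if sig is not None and round_sig_figs(computed, sig) == printed:
        return True
    return abs(computed - printed) <= rel_tol * abs(printed)
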