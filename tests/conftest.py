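"""Shared fixtures.  Oscillator simulations are session-scoped: they are the
expensive part of the suite and are reused across modules."""

import pytest

from navsim import (
    bank_response,
    build_complete_rulebase,
    build_default_map,
    default_bank,
)
from navsim.what_stream import LAMBDA_AD, LAMBDA_HEALTHY


@pytest.fixture(scope="session")
def default_map():
    return build_default_map()


@pytest.fixture(scope="session")
def rulebase(default_map):
    return build_complete_rulebase(default_map)


@pytest.fixture(scope="session")
def healthy_responses_code4():
    """Healthy six-unit bank (lambda=0.2, B=1.5, As=1) driven at code 4."""
    return bank_response(default_bank(lam=LAMBDA_HEALTHY), 4.0)


@pytest.fixture(scope="session")
def ad_responses_by_code():
    """AD bank (lambda=15.2) driven at every route code 4..9."""
    bank = default_bank(lam=LAMBDA_AD)
    return {code: bank_response(bank, float(code)) for code in range(4, 10)}
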