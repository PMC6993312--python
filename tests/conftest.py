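from hypothesis import settings

import pytest

import prophyflag as pf

settings.register_profile("suite", max_examples=40, derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lexicon():
    return pf.default_lexicon()


@pytest.fixture(scope="session")
def final_variant():
    return pf.FINAL_VARIANT
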