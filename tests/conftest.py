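import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from notelex.lexicon import build_default_lexicon
from notelex.simulate import default_template_bank


@pytest.fixture(scope="session")
def lexicon():
    return build_default_lexicon()


@pytest.fixture(scope="session")
def bank():
    return default_template_bank()
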