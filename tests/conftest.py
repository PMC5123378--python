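import pytest

from lodn.simulate import builtin_truth_sets


@pytest.fixture(scope="session")
def truth_sets():
    return builtin_truth_sets()
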