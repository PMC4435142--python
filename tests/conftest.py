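import pytest

from odorvector import datasets


@pytest.fixture(scope="session")
def registry():
    return datasets.load_reference_thresholds()


@pytest.fixture(scope="session")
def reference_samples():
    return datasets.load_reference_mixtures()


@pytest.fixture(scope="session")
def reference_predictions():
    return datasets.load_reference_predictions()
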