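import pytest

from metseg.synthetic import default_band_map


@pytest.fixture(scope="session")
def band_map():
    return default_band_map()


@pytest.fixture(scope="session")
def q_bands(band_map):
    return [b for b in band_map if b.arm == "q"]
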