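import pytest

from mipscreen.genemodel import build_fixture_gene_model
from mipscreen.panel import tile_panel


@pytest.fixture(scope="session")
def model():
    return build_fixture_gene_model(seed=1)


@pytest.fixture(scope="session")
def panel(model):
    return tile_panel(model)
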