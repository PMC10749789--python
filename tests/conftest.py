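import numpy as np
import pytest

import histoexpr as hx


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_sections():
    """The default desk-scale synthetic benchmark (4 sections, 8x8 spots)."""
    sections, truths = hx.make_dataset(hx.SynthConfig())
    return sections, truths


@pytest.fixture()
def tiny_section():
    """One small section for fast wiring tests: 4x4 spots, 10 genes."""
    cfg = hx.SynthConfig(n_sections=1, grid_rows=4, grid_cols=4,
                         spot_spacing=56, n_genes=10, seed=7)
    image, spots, expr, gt = hx.make_section(cfg, 0)
    return hx.Section(spots=spots, expr=expr, image=image), gt
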