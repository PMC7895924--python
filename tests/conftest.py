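import numpy as np
import pytest

from mosaictile import synthetic as syn


@pytest.fixture(scope="session")
def hex_tess():
    """Periodic 12x12 hexagonal lattice (144 cells, 300x300 px)."""
    return syn.generate_tessellation(
        syn.TessellationSpec(
            n_cells=144, domain_size=(300, 300), periodic=True,
            lattice_mode="hexagonal", seed=0,
        )
    )


@pytest.fixture(scope="session")
def hex_raster(hex_tess):
    labels, truth = syn.rasterize_labels(hex_tess)
    return labels, truth


@pytest.fixture(scope="session")
def voronoi_tess():
    """Periodic Lloyd-relaxed Voronoi tessellation (300 cells)."""
    return syn.generate_tessellation(
        syn.TessellationSpec(n_cells=300, domain_size=(400, 400), periodic=True, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
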