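import math

import numpy as np
import pytest

from liposort import (
    GenotypeSpec,
    ImagingConfig,
    LiposomeState,
    OscillationState,
    PopulationConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def imaging():
    return ImagingConfig()


@pytest.fixture(scope="session")
def big_mock_sample():
    """~100k liposomes from the 1:39 mock mixture (shared across test modules)."""
    from liposort import sample_population

    yfp = GenotypeSpec(name="YFP", phenotype="lumen")
    ctrl = GenotypeSpec(name="btubB", phenotype="none")
    cfg = PopulationConfig(components=[(yfp, 1 / 40), (ctrl, 39 / 40)],
                           n_fov=1200, seed=20240601)
    flat = [lp for fov in sample_population(cfg) for lp in fov]
    assert len(flat) >= 100_000
    return flat


@pytest.fixture
def mock_1to39():
    """A 1:39 two-gene mock mixture (reporter vs dark control)."""
    yfp = GenotypeSpec(name="YFP", phenotype="lumen")
    ctrl = GenotypeSpec(name="btubB", phenotype="none")
    return PopulationConfig(components=[(yfp, 1 / 40), (ctrl, 39 / 40)])


def make_liposome(x, y, diameter=9.0, mode="static_lumen", period=None, phase=0.0,
                  expressing=True, phenotype="lumen", name="G", lid=0, axis=0.0):
    osc = OscillationState(mode=mode, period_s=period, phase=phase, axis_angle=axis)
    return LiposomeState(
        id=lid,
        genotype=GenotypeSpec(name=name, phenotype=phenotype),
        center_um=(x, y),
        diameter_um=diameter,
        expressing=expressing,
        osc=osc,
    )


@pytest.fixture
def grid_population():
    """16 well-separated vesicles on a grid, half membrane-bound, half lumen."""
    pop = []
    for i in range(16):
        x = 20.0 + 30.0 * (i % 4)
        y = 20.0 + 30.0 * (i // 4)
        mode = "static_membrane" if i % 2 == 0 else "static_lumen"
        phen = "membrane" if i % 2 == 0 else "lumen"
        pop.append(make_liposome(x, y, diameter=8.0 + (i % 3), mode=mode,
                                 phenotype=phen, lid=i))
    return pop
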