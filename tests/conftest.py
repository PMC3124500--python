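import numpy as np
import pandas as pd
import pytest

from riqtl import simulate as sim
from riqtl.panel import RIPanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """Hand-built 6-strain, 5-marker panel on two chromosomes."""
    markers = pd.DataFrame(
        {
            "marker": ["m1", "m2", "m3", "m4", "m5"],
            "chromosome": ["1", "1", "1", "2", "2"],
            "position_cM": [0.0, 10.0, 20.0, 0.0, 15.0],
            "position_Mb": [0.0, 20.0, 40.0, 0.0, 30.0],
        }
    )
    genotypes = np.array(
        [
            ["A", "A", "A", "B", "B", "B"],
            ["A", "A", "B", "B", "B", "A"],
            ["A", "B", "B", "B", "A", "A"],
            ["B", "A", "B", "A", "B", "A"],
            ["B", "A", "B", "A", "A", "B"],
        ]
    )
    return RIPanel([f"S{i}" for i in range(1, 7)], markers, genotypes)


@pytest.fixture(scope="session")
def axbxa_panel():
    """26-strain, ~2000-marker panel with RI linkage structure."""
    cfg = sim.axbxa_like_config(seed=7)
    return sim.simulate_ri_genotypes(cfg)


@pytest.fixture(scope="session")
def qtl_config():
    return sim.axbxa_like_config(
        seed=7,
        qtl=sim.QTLSpec(chromosome="5", position_cM=40.0, additive_effect=2.0),
        strain_sd=1.0,
        trait_baseline=100.0,
    )
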