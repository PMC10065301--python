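import numpy as np
import pytest

import nichecast as nc
from nichecast.synthetic import default_geometry


@pytest.fixture(scope="session")
def toy():
    """The fully enumerated 6x6 fixture: (stack, occurrences, suitability, expected)."""
    return nc.make_toy_fixture()


@pytest.fixture()
def small_grid():
    """A 10x8 grid with two nodata holes."""
    vals = np.arange(80, dtype=float).reshape(10, 8)
    vals[0, 0] = vals[7, 3] = -9999.0
    return nc.RasterGrid(100.0, 20.0, 0.5, -9999.0, vals)


@pytest.fixture(scope="session")
def small_suite():
    """A 40x40 synthetic landscape with known truth, shared across tests."""
    geom = default_geometry(40, 40)
    spec = nc.TruthSpec(
        true_weights={"env01": 3.0},
        optimum_style="linear",
        target_pairwise_r={("env01", "env03"): 0.9},
        smoothness=4.0,
        warming_shift={"env01": 0.8},
    )
    stack = nc.make_env_stack(4, geom, spec, seed=101)
    truth = nc.true_suitability(stack, spec)
    occ = nc.sample_thinned_occurrences(truth, 60, seed=102)
    return stack, spec, truth, occ


@pytest.fixture(scope="session")
def small_model(small_suite):
    """A fitted linear-feature model on the small suite."""
    stack, spec, truth, occ = small_suite
    background = nc.sample_background(stack, occ, 10_000, seed=103)
    feats = nc.build_features(stack, occ, background, "L")
    model = nc.fit(feats, 1.0)
    return stack, occ, background, feats, model
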