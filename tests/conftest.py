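import numpy as np
import pandas as pd
import pytest

from enmshift import synthworld as sw
from enmshift.geodata import EnvStack, GridHeader, Raster


@pytest.fixture(scope="session")
def world():
    """Default synthetic world (current stack, scenarios, true niche)."""
    cfg = sw.default_config(seed=42)
    current, scenarios, niche = sw.make_world(cfg)
    return current, scenarios, niche


@pytest.fixture(scope="session")
def presences(world):
    current, _, niche = world
    return sw.sample_presences(current, niche, 150, seed=421)


@pytest.fixture
def small_header():
    return GridHeader(ncols=4, nrows=3, xll=100.0, yll=40.0, cellsize=0.5)


@pytest.fixture
def small_stack(small_header):
    rng = np.random.default_rng(0)
    a = Raster(small_header, rng.normal(10, 2, (3, 4)))
    b = Raster(small_header, rng.normal(0, 1, (3, 4)))
    return EnvStack({"a": a, "b": b})


@pytest.fixture(scope="session")
def toy_fit():
    """A small fitted LQ model with its diagnostics and data tables."""
    from enmshift.engine import MaxEntFitter
    from enmshift.features import FeatureSpec

    rng = np.random.default_rng(7)
    bg = pd.DataFrame({"x": rng.normal(0, 1, 400), "y": rng.normal(0, 1, 400)})
    pres = pd.DataFrame({"x": rng.normal(1.0, 0.4, 30), "y": rng.normal(0, 1, 30)})
    fitter = MaxEntFitter(FeatureSpec.from_label("LQ"), rm=1.0, max_iter=5000, tol=1e-10)
    model, diag = fitter.fit(pres, bg)
    return model, diag, pres, bg
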