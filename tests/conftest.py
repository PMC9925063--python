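import numpy as np
import pandas as pd
import pytest

import coralkrige as ck


@pytest.fixture(scope="session")
def small_world():
    """Default-parameter synthetic world, shared across tests."""
    return ck.make_world(seed=7)


@pytest.fixture(scope="session")
def small_world_run(small_world):
    """Full pipeline result on the shared world."""
    w = small_world
    cfg = ck.PipelineConfig(
        years=(w.params.model_years[0], w.params.model_years[-1]),
        climatology_years=w.params.climatology_years,
    )
    return ck.run_pipeline(w.reports, w.sst, w.mask, regions=w.regions, config=cfg), cfg


@pytest.fixture
def toy_mask():
    """A 3x3 block of reef cells near the origin."""
    cells = [ck.CellIndex(3600 + di, 1800 + dj) for di in range(3) for dj in range(3)]
    return ck.ReefMask(cells)


def equatorial_points(distances_km):
    """(lats, lons) of points spaced along the equator at given km offsets."""
    lats = np.zeros(len(distances_km))
    lons = np.degrees(np.asarray(distances_km, dtype=float) / 6371.0)
    return lats, lons


@pytest.fixture
def flat_sst_series():
    """One year of constant 28 C daily SST."""
    dates = pd.date_range("2000-01-01", "2000-12-31", freq="D")
    return ck.SSTSeries(cell=None, dates=dates, sst=np.full(len(dates), 28.0))
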