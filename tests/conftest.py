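import dataclasses

import numpy as np
import pytest

import wetstage as ws
from wetstage.grid import GridSpec, RasterBand


@pytest.fixture
def small_grid():
    return GridSpec(origin_x=0.0, origin_y=100.0, pixel_size=10.0,
                    n_rows=10, n_cols=10, crs_label="test")


def band_from(grid, values, name="b", units="index"):
    return RasterBand(grid=grid, name=name,
                      values=np.broadcast_to(np.asarray(values, dtype=float),
                                             grid.shape).copy(),
                      units=units)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared by the read-only tests."""
    return ws.generate_study(ws.GenerativeSpec(seed=11))


@pytest.fixture(scope="session")
def default_fit(default_study):
    """Pooled two-stage fit of the default study (read-only)."""
    s = default_study
    res = ws.run_pipeline(s.scenes, s.wetlands, s.samples, climate=s.climate,
                          nutrient="N", seed=11, with_importance=False)
    return res


@pytest.fixture(scope="session")
def tiny_spec():
    """A miniature generative spec for fast end-to-end CLI runs."""
    import datetime as dt
    return dataclasses.replace(
        ws.GenerativeSpec(seed=3),
        grid=GridSpec(origin_x=0.0, origin_y=600.0, pixel_size=10.0,
                      n_rows=60, n_cols=60, crs_label="tiny"),
        months=[dt.date(2021, m, 15) for m in range(3, 9)],
    )
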