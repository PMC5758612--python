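import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import latmask as lm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixtures():
    return lm.load_fixtures()


@pytest.fixture(scope="session")
def te_table(fixtures):
    return lm.compute_TE(fixtures.table2)


@pytest.fixture(scope="session")
def small_geometry():
    """Odd-sized raster: the display center falls on a pixel center."""
    return lm.DisplayGeometry(width_px=129, height_px=257, arcmin_per_pixel=2.14)


@pytest.fixture()
def flat_observer():
    """Observer with a 0.2 orthogonal threshold and a null TE profile."""
    return lm.ObserverModel(
        orthogonal_threshold={3.0: 0.2, 4.0: 0.2, 6.0: 0.2, 8.0: 0.2},
        profile=lm.LateralProfile({3.0: 0.0, 8.0: 0.0}),
    )


def make_threshold_table(rows):
    """rows: (participant, group, phase, orientation, separation, threshold)."""
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "group",
            "phase",
            "orientation",
            "separation",
            "threshold",
        ],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
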