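from __future__ import annotations

import numpy as np
import pytest

from marshres.landscape import (
    ClassInfo,
    ClassTable,
    DEFAULT_CLASS_TABLE,
    ElevationGrid,
    ErodibilityGrid,
    LandCoverGrid,
    TidalSurface,
    generate_landscape,
)

CELL = 30.0


def make_landcover(codes, nodata=-1):
    codes = np.asarray(codes)
    return LandCoverGrid(codes, CELL, (0.0, codes.shape[0] * CELL), nodata=nodata)


def make_elevation(elev):
    elev = np.asarray(elev, dtype=float)
    return ElevationGrid(elev, CELL, (0.0, elev.shape[0] * CELL))


def make_erodibility(k):
    k = np.asarray(k, dtype=float)
    return ErodibilityGrid(k, CELL, (0.0, k.shape[0] * CELL))


@pytest.fixture(scope="session")
def class_table() -> ClassTable:
    return DEFAULT_CLASS_TABLE


@pytest.fixture(scope="session")
def small_landscape():
    return generate_landscape(seed=1, n_units=6, grid_shape=(60, 60), marsh_fraction=0.3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_landcover(rng, shape=(20, 20), p_nodata=0.0):
    codes = rng.choice(list(DEFAULT_CLASS_TABLE.entries), size=shape)
    if p_nodata > 0:
        codes[rng.random(shape) < p_nodata] = -1
    return make_landcover(codes)


def full_mask(shape):
    return np.ones(shape, dtype=bool)


def simple_tides(mhhw=1.2, mtl=0.2, mllw=-0.8):
    return TidalSurface(mhhw=mhhw, mtl=mtl, mllw=mllw)
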