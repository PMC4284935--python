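"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from onhcolor.hb import HbMap, LensCompensation
from onhcolor.segmentation import DiscGeometry, DiscRegions, VesselMask
from onhcolor.synth import SubjectSpec, render_fundus


@pytest.fixture(scope="session")
def rendered_default():
    """One default rendered subject (healthy sector means, mild noise)."""
    return render_fundus(SubjectSpec(seed=11))


@pytest.fixture(scope="session")
def rendered_noiseless():
    return render_fundus(SubjectSpec(seed=11, noise_sd=0.0))


@pytest.fixture()
def small_disc_regions():
    """A compact hand-built scene: 64x64 grid, disc radius 20, ring of vessel
    pixels near the center.  Small enough for brute-force pixel loops."""
    shape = (64, 64)
    disc = DiscGeometry(center=(32.0, 32.0), radius_x=20.0, radius_y=20.0)
    interior = disc.interior_mask(shape)
    rng = np.random.default_rng(0)
    vessels = np.zeros(shape, dtype=bool)
    ys, xs = np.nonzero(interior)
    pick = rng.choice(len(ys), size=120, replace=False)
    vessels[ys[pick], xs[pick]] = True
    return DiscRegions(
        disc=disc,
        vessels=VesselMask(vessels),
        tissue=interior & ~vessels,
    )


@pytest.fixture()
def uniform_hb_map(small_disc_regions):
    """HbMap with constant tissue value 70 on the small scene."""
    values = np.full((64, 64), np.nan, dtype=np.float32)
    values[small_disc_regions.tissue] = 70.0
    values[small_disc_regions.vessels.mask] = 100.0
    return HbMap(
        values=values,
        vessel_reference=(0.6, 0.15),
        regions=small_disc_regions,
        compensation=LensCompensation.identity(),
    )
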