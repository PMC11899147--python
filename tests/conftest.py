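"""Shared fixtures: the study phantom and its derived angiography products.

The default phantom (one large superficial vessel shadowing static tissue,
one small deep vessel) is expensive enough to build once per session; tests
that need the full decorrelation comparison share the products.
"""

from dataclasses import replace

import numpy as np
import pytest

from oacd.angiography import decorrelate, detect_surface, enface_project, split_slabs
from oacd.attenuation import oac_volume
from oacd.phantom import default_phantom_spec, make_phantom

PHANTOM_SEED = 20260928


@pytest.fixture(scope="session")
def study_phantom():
    """Default two-vessel phantom volume + ground truth."""
    spec = default_phantom_spec(seed=PHANTOM_SEED)
    volume, truth = make_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def angio_products(study_phantom):
    """Amplitude and OAC decorrelation volumes plus en-face slabs."""
    spec, volume, truth = study_phantom
    surface = detect_surface(volume.data)
    mu = oac_volume(volume)
    out = {"surface": surface}
    for name, signal in (("amplitude", np.sqrt(volume.data)), ("oac", mu.mu)):
        D = decorrelate(signal)
        sup3, deep3 = split_slabs(D, surface, volume.delta)
        out[name] = {
            "D": D,
            "superficial": enface_project(sup3, slab="superficial", provenance=name).pixels,
            "deep": enface_project(deep3, slab="deep", provenance=name).pixels,
        }
    return out


@pytest.fixture(scope="session")
def single_vessel_phantom():
    """Phantom with only the large superficial vessel (no deep vessel)."""
    spec = default_phantom_spec(seed=PHANTOM_SEED + 1)
    spec = replace(spec, vessels=spec.vessels[:1])
    volume, truth = make_phantom(spec)
    return spec, volume, truth


def subvessel_static_mask(spec, truth):
    """Static voxels strictly beneath the superficial vessel footprint."""
    vessel = spec.vessels[0]
    x0 = int(vessel.centerline[0][0])
    r = int(np.ceil(vessel.radius))
    nz = spec.grid[1]
    z_bottom = int(vessel.centerline[0][2]) + r
    mask = np.zeros(truth.vessel_mask_3d.shape, dtype=bool)
    mask[z_bottom + 3:min(z_bottom + 60, nz - 40), x0 - r:x0 + r + 1, :] = True
    mask &= ~truth.vessel_mask_3d
    return mask
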