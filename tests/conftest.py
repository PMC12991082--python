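"""Shared phantom fixtures; everything is generated at test time."""

import numpy as np
import pytest

from vasotrace import synthgen as sg


@pytest.fixture(scope="session")
def straight_tube():
    """Straight tube of radius 2, axis length 60 voxels, isotropic 1 um."""
    spec = sg.VascularPhantomSpec(
        volume_shape=(64, 16, 64),
        branches=(sg.Branch(((2, 8, 32), (61, 8, 32)), 2.0),),
        voxel_size_um=(1.0, 1.0, 1.0),
    )
    return spec, sg.generate_vascular_volume(spec)


@pytest.fixture(scope="session")
def semicircle_phantom():
    """Semicircular branch, radius of curvature 50 voxels, analytic tau = pi/2."""
    radius = 50.0
    ang = np.linspace(0.0, np.pi, 60)
    pts = tuple((5 + radius * np.sin(a), 8.0, 5 + radius * (1 - np.cos(a)))
                for a in ang)
    spec = sg.VascularPhantomSpec(
        volume_shape=(60, 16, 110),
        branches=(sg.Branch(pts, 2.0),),
        voxel_size_um=(1.0, 1.0, 1.0),
    )
    return spec, sg.generate_vascular_volume(spec)


@pytest.fixture(scope="session")
def y_phantom():
    """Three branches meeting at one point: 1 junction, 3 endpoints."""
    center = (32, 8, 32)
    spec = sg.VascularPhantomSpec(
        volume_shape=(64, 16, 64),
        branches=(
            sg.Branch((center, (10, 8, 10)), 2.0),
            sg.Branch((center, (10, 8, 54)), 2.0),
            sg.Branch((center, (60, 8, 32)), 2.0),
        ),
        voxel_size_um=(1.0, 1.0, 1.0),
    )
    return spec, sg.generate_vascular_volume(spec)


def sinusoid_branch_spec(amplitude, seed=0, n_cycles=2.0, shape=(100, 20, 40)):
    """Single sinusoidal branch with analytically known (sampled) tortuosity."""
    t = np.linspace(0.0, 1.0, 60)
    pts = tuple((5 + (shape[0] - 10) * ti, shape[1] / 2,
                 shape[2] / 2 + amplitude * np.sin(2 * np.pi * n_cycles * ti))
                for ti in t)
    return sg.VascularPhantomSpec(volume_shape=shape,
                                  branches=(sg.Branch(pts, 2.0),),
                                  voxel_size_um=(1.0, 1.0, 1.0), seed=seed)
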