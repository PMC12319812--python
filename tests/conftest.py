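"""Shared fixtures: small phantoms, spherical conductors and sensor rings.

Everything is generated programmatically and seeded; session scope keeps
the expensive geometry builds to one per run.
"""

import numpy as np
import pytest
import trimesh

from pseudomri import synthetic as syn
from pseudomri.forward import ConductorModel
from pseudomri.geometry import TriangleMesh, VoxelVolume
from pseudomri.sensors import SensorArray


@pytest.fixture(scope="session")
def small_phantom():
    """64^3 @ 3 mm head phantom with 78 cortical regions."""
    return syn.make_phantom_anatomy(64, 3.0, 78, seed=1)


@pytest.fixture(scope="session")
def head_mask(small_phantom):
    gt = small_phantom
    return VoxelVolume((np.asarray(gt.anatomy.data) > 10).astype(np.uint8),
                       gt.anatomy.affine)


@pytest.fixture(scope="session")
def shell_mesh():
    """Closed spherical shell, radius 80 mm, centred at the origin."""
    ico = trimesh.creation.icosphere(subdivisions=3, radius=80.0)
    return TriangleMesh(np.array(ico.vertices), np.array(ico.faces))


def ring_sensors(n_sites=30, radius=110.0, seed=1) -> SensorArray:
    """Triaxial sensors on a sphere of given radius about the origin."""
    rng = np.random.default_rng(seed)
    pos, ori, labels, sid = [], [], [], []
    for i in range(n_sites):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        t1 = np.cross(u, (0.0, 0.0, 1.0))
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(u, (0.0, 1.0, 0.0))
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(u, t1)
        for ax, o in zip("ZXY", (u, t1, t2)):
            pos.append(u * radius)
            ori.append(o)
            labels.append(f"S{i:02d}-{ax}")
            sid.append(i)
    return SensorArray(np.array(pos), np.array(ori), labels, np.array(sid))


@pytest.fixture(scope="session")
def sphere_sensors():
    return ring_sensors()


@pytest.fixture(scope="session")
def sphere_conductor():
    return ConductorModel.sphere(np.zeros(3), 80.0)
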