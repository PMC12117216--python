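"""Shared fixtures: small phantoms and session-scoped transport runs.

The head-transmission runs are the expensive fixtures; they are computed
once per session and shared between the unit tests and the acceptance
checks. Problem sizes are desk-scale (see docs/methods.md).
"""

import numpy as np
import pytest

import headphoton as hp
from headphoton.phantom import LayerOpticalProperties


@pytest.fixture(scope="session")
def head_pitch1():
    """Default six-layer 155 mm head phantom at 1 mm pitch."""
    return hp.build_layered_head_phantom(voxel_pitch=1.0)


@pytest.fixture(scope="session")
def head_geometry(head_pitch1):
    """Diametric source/detector placement on the lateral (x) axis."""
    center = np.asarray(head_pitch1.meta["center_mm"])
    a = head_pitch1.meta["outer_semi_axes_mm"][0]
    source = hp.SourceSpec((center[0] - a, center[1], center[2]), (1.0, 0.0, 0.0))
    detector = hp.DetectorSpec((center[0] + a, center[1], center[2]), 40.0)
    return {"center": center, "a_lat": a, "source": source, "detector": detector,
            "sdd": 2 * a}


@pytest.fixture(scope="session")
def head_transmission_run(head_pitch1, head_geometry):
    """Diametric transmission run on the default head (2-in source,
    4-cm-radius detector patch), 3.5M packets."""
    cfg = hp.SimulationConfig(n_packets=3_500_000, seed=11)
    records, fluence, summary = hp.run_simulation(
        head_pitch1, head_geometry["source"], head_geometry["detector"], cfg)
    return records, fluence, summary


@pytest.fixture(scope="session")
def head_jacobian_runs(head_pitch1, head_geometry):
    """Two voxel-path-recording runs with a generous surface patch
    (depth-crop detector): reference source height and 40 mm lower."""
    center = head_geometry["center"]
    a = head_geometry["a_lat"]
    det = hp.DetectorSpec(mode="depth_crop", crop_depth=100.0)
    cfg = hp.SimulationConfig(n_packets=250_000, seed=23,
                              record_voxel_paths=True)
    out = {}
    for name, drop in (("reference", 0.0), ("lowered", 40.0)):
        src = hp.SourceSpec((center[0] - a, center[1], center[2] - drop),
                            (1.0, 0.0, 0.0))
        records, _, _ = hp.run_simulation(head_pitch1, src, det, cfg)
        out[name] = records
    return out


@pytest.fixture(scope="session")
def scattering_cube():
    """(20 mm)^3 homogeneous scattering cube for Jacobian checks."""
    props = LayerOpticalProperties(1, "medium", 0.01, 1.0, 0.0, 1.0)
    return hp.build_homogeneous_cube(20.0, props, voxel_pitch=1.0)


@pytest.fixture
def clear_cube():
    """Non-scattering, non-absorbing 155 mm cube with matched boundaries."""
    props = LayerOpticalProperties(1, "clear", 0.0, 0.0, 0.0, 1.37)
    cube = hp.build_homogeneous_cube(155.0, props, voxel_pitch=5.0)
    cube.ambient_n = 1.37
    return cube
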