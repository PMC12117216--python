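"""Phantom builders: geometry, optical properties, surface patches, I/O."""

import numpy as np
import pytest
from scipy import ndimage

import headphoton as hp
from headphoton.phantom import (
    LayerOpticalProperties,
    acceptance_mask,
    build_layered_head_phantom,
    build_slab_phantom,
    default_head_layers,
    load_nifti,
    save_nifti,
    surface_patch,
)

TABLE = {
    # label: (mu_a, mu_s, g, n)
    1: (0.045, 19.818, 0.89, 1.37),   # scalp
    2: (0.011, 17.4545, 0.89, 1.37),  # skull
    3: (0.0026, 0.0909, 0.89, 1.37),  # CSF
    4: (0.028, 7.3, 0.89, 1.37),      # gray matter
    5: (0.092, 38.0, 0.87, 1.37),     # white matter
    6: (0.0, 0.0, 1.0, 1.0),          # air cavities
}


def test_default_layer_table_values():
    """The six default layers carry the published 810 nm coefficients exactly."""
    layers = default_head_layers()
    assert len(layers) == 6
    for lab, (mua, mus, g, n) in TABLE.items():
        p = layers[lab]
        assert (p.mu_a, p.mu_s, p.g, p.n) == (mua, mus, g, n)
    # reduced scattering is derived consistently
    assert layers[5].mu_s_prime == pytest.approx(38.0 * 0.13)
    assert layers[6].mu_s_prime == 0.0


def test_layer_property_validation():
    with pytest.raises(ValueError):
        LayerOpticalProperties(1, "bad", -0.1, 1.0, 0.0, 1.4)
    with pytest.raises(ValueError):
        LayerOpticalProperties(1, "bad", 0.1, 1.0, 1.5, 1.4)
    with pytest.raises(ValueError):
        LayerOpticalProperties(1, "bad", 0.1, 1.0, 0.5, 0.9)


def test_head_lateral_extent(head_pitch1):
    """Widest inside-the-head span along the lateral axis is 155 mm +/- 1 voxel."""
    inside = head_pitch1.inside_mask()
    span = inside.any(axis=(1, 2))
    extent = span.sum() * head_pitch1.voxel_pitch
    assert abs(extent - 155.0) <= 1.0 + 1e-9


def test_head_is_deterministic():
    a = build_layered_head_phantom(lateral_diameter=60, voxel_pitch=2.0,
                                   layer_thicknesses={"scalp": 3, "skull": 3,
                                                      "csf": 2, "gray_matter": 2})
    b = build_layered_head_phantom(lateral_diameter=60, voxel_pitch=2.0,
                                   layer_thicknesses={"scalp": 3, "skull": 3,
                                                      "csf": 2, "gray_matter": 2})
    np.testing.assert_array_equal(a.labels, b.labels)


def test_degenerate_single_layer_head():
    """All thickness on one shell collapses the head to a homogeneous ellipsoid."""
    ph = build_layered_head_phantom(
        lateral_diameter=40.0, voxel_pitch=1.0,
        layer_thicknesses={"scalp": 19.0, "skull": 0.0, "csf": 0.0,
                           "gray_matter": 0.0})
    labs = set(np.unique(ph.labels)) - {0}
    # scalp shell plus the (tiny) white-matter core the remainder leaves
    inside = ph.inside_mask().sum()
    scalp = (ph.labels == 1).sum()
    assert scalp / inside > 0.99


def test_excessive_shell_thickness_names_layer():
    with pytest.raises(ValueError, match="skull"):
        build_layered_head_phantom(
            lateral_diameter=80.0, voxel_pitch=1.0, si_diameter=30.0,
            layer_thicknesses={"scalp": 10.0, "skull": 6.0, "csf": 1.0,
                               "gray_matter": 1.0})
    with pytest.raises(ValueError, match="lateral_diameter"):
        build_layered_head_phantom(
            lateral_diameter=35.0, voxel_pitch=1.0,
            layer_thicknesses={"scalp": 10.0, "skull": 10.0, "csf": 2.0,
                               "gray_matter": 2.0})


def test_shell_volume_fractions_match_analytic():
    """Voxel counts x pitch^3 reproduce closed-form ellipsoidal-shell volumes."""
    ph = build_layered_head_phantom(voxel_pitch=0.5)
    bounds = [np.asarray(b) for b in ph.meta["boundary_semi_axes_mm"]]
    vol = [4.0 / 3.0 * np.pi * np.prod(b) for b in bounds]
    shells = {1: vol[0] - vol[1], 2: vol[1] - vol[2], 3: vol[2] - vol[3],
              4: vol[3] - vol[4], 5: vol[4]}
    pitch3 = ph.voxel_pitch**3
    for lab, v_true in shells.items():
        v_mc = (ph.labels == lab).sum() * pitch3
        assert v_mc == pytest.approx(v_true, rel=0.02), f"label {lab}"


def test_csf_shell_is_connected_and_separating(head_pitch1):
    """CSF forms one connected shell; gray matter never touches skull."""
    csf = head_pitch1.labels == 3
    _, n_comp = ndimage.label(csf, structure=np.ones((3, 3, 3)))
    assert n_comp == 1
    gm = head_pitch1.labels == 4
    skull_dilated = ndimage.binary_dilation(head_pitch1.labels == 2)
    assert not (gm & skull_dilated).any()


def test_air_cavity_inclusion():
    ph = build_layered_head_phantom(
        lateral_diameter=80, voxel_pitch=1.0,
        layer_thicknesses={"scalp": 4, "skull": 5, "csf": 2, "gray_matter": 3},
        air_cavity={"center": (42.0, 49.0, 45.0), "semi_axes": (6.0, 6.0, 6.0)})
    assert (ph.labels == 6).any()
    assert 6 in ph.layer_table and ph.layer_table[6].n == 1.0


def test_slab_phantom_geometry():
    props = default_head_layers()[5]
    slab = build_slab_phantom(100.0, props, lateral_size=50.0, voxel_pitch=2.0)
    inside = slab.inside_mask()
    # voxel count along the normal equals round(thickness / pitch)
    assert inside.any(axis=(1, 2)).sum() == round(100.0 / 2.0)
    one = build_slab_phantom(2.0, props, lateral_size=10.0, voxel_pitch=2.0)
    assert one.inside_mask().any(axis=(1, 2)).sum() == 1
    with pytest.raises(ValueError):
        build_slab_phantom(-1.0, props)


def test_surface_patch_modes(head_pitch1, head_geometry):
    det = head_geometry["detector"]
    faces, centers = surface_patch(head_pitch1, det)
    assert len(faces) > 0
    d = np.linalg.norm(centers - np.asarray(det.sphere_center), axis=1)
    assert (d <= det.sphere_radius + 1e-9).all()
    # patch area grows monotonically with radius
    areas = []
    for radius in (10.0, 20.0, 40.0):
        f, _ = surface_patch(head_pitch1, hp.DetectorSpec(det.sphere_center, radius))
        areas.append(len(f))
    assert areas[0] < areas[1] < areas[2]
    # empty intersection raises
    with pytest.raises(ValueError, match="does not touch"):
        surface_patch(head_pitch1, hp.DetectorSpec((0.0, 0.0, 0.0), 1.0))
    # depth_crop mode needs the source and respects the crop depth
    src = head_geometry["source"]
    f2, c2 = surface_patch(head_pitch1, hp.DetectorSpec(mode="depth_crop",
                                                        crop_depth=133.0), source=src)
    depth = (c2 - np.asarray(src.center)) @ np.asarray(src.direction)
    assert (depth >= 133.0 - 1e-9).all()
    mask = acceptance_mask(head_pitch1, f2)
    assert mask.sum() == len(f2)


def test_detector_spec_validation():
    with pytest.raises(ValueError):
        hp.DetectorSpec((0, 0, 0), 0.0)
    with pytest.raises(ValueError):
        hp.DetectorSpec(mode="depth_crop", crop_depth=0.0)
    with pytest.raises(ValueError):
        hp.SourceSpec((0, 0, 0), (1.0, 0.5, 0.0))


def test_nifti_roundtrip(tmp_path):
    ph = build_layered_head_phantom(
        lateral_diameter=50, voxel_pitch=2.0,
        layer_thicknesses={"scalp": 3, "skull": 3, "csf": 2, "gray_matter": 2})
    path = tmp_path / "head.nii.gz"
    save_nifti(ph, path)
    back = load_nifti(path)
    np.testing.assert_array_equal(back.labels, ph.labels)
    assert back.voxel_pitch == ph.voxel_pitch
    assert back.layer_table[3].mu_s == ph.layer_table[3].mu_s
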