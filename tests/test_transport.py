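"""Transport engine: scattering kernel, boundaries, conservation, profiles."""

import numpy as np
import pytest

import headphoton as hp
from headphoton.phantom import LayerOpticalProperties
from headphoton.transport import fresnel_reflectance, sample_henyey_greenstein


class TestHenyeyGreenstein:
    def test_isotropic_closed_form(self):
        assert sample_henyey_greenstein(0.0, 0.25) == pytest.approx(0.5)
        assert sample_henyey_greenstein(0.0, 0.0) == pytest.approx(1.0)

    def test_anisotropic_closed_form(self):
        # (1/(2g)) [1 + g^2 - ((1-g^2)/(1-g+2gu))^2] at g=0.89, u=0.5
        assert sample_henyey_greenstein(0.89, 0.5) == pytest.approx(0.98251, abs=1e-5)

    def test_forward_delta(self):
        assert sample_henyey_greenstein(1.0, 0.7) == 1.0

    def test_mean_cosine_equals_g(self):
        rng = np.random.default_rng(42)
        u = rng.random(10**6)
        c = sample_henyey_greenstein(0.87, u)
        se = c.std() / np.sqrt(c.size)
        assert abs(c.mean() - 0.87) < 3 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sample_henyey_greenstein(0.5, 1.0)
        with pytest.raises(ValueError):
            sample_henyey_greenstein(1.5, 0.5)


def test_fresnel_normal_incidence():
    """Normal-incidence reflectance at a tissue/air interface: ((n1-n2)/(n1+n2))^2."""
    assert fresnel_reflectance(1.37, 1.0, 1.0) == pytest.approx(
        (0.37 / 2.37) ** 2, abs=1e-6)
    assert fresnel_reflectance(1.0, 1.0, 0.6) == 0.0
    # beyond the critical angle: total internal reflection
    cos_c = np.sqrt(1 - (1.0 / 1.37) ** 2)
    assert fresnel_reflectance(1.37, 1.0, 0.9 * cos_c) == 1.0


def test_ballistic_crossing_time(clear_cube):
    """A packet crosses 155 mm of clear n=1.37 medium in L*n/c ns."""
    center = np.asarray(clear_cube.shape) * clear_cube.voxel_pitch / 2
    event, rec, _ = hp.propagate_packet(
        (0.5, center[1], center[2]), (1, 0, 0), clear_cube,
        hp.SimulationConfig(n_packets=1, max_time=50.0), seed=3)
    assert event == "exited"
    assert rec.total_path == pytest.approx(155.0, abs=1e-6)
    assert rec.exit_time == pytest.approx(155.0 * 1.37 / 299.792458, rel=1e-9)


def test_no_absorption_exit_weight_is_unity():
    """With mu_a = 0 everywhere and roulette out of reach, exit weight is 1."""
    props = LayerOpticalProperties(1, "scatter_only", 0.0, 2.0, 0.0, 1.0)
    cube = hp.build_homogeneous_cube(20.0, props, voxel_pitch=1.0)
    cfg = hp.SimulationConfig(n_packets=200, seed=7, roulette_threshold=1e-300,
                              max_time=1e6)
    records, _, summary = hp.run_simulation(
        cube, hp.SourceSpec((2.0, 12.0, 12.0), (1, 0, 0), diameter=0.0), None, cfg)
    assert summary.conservation_error < 1e-6
    assert np.all(records.weight == 1.0)


def test_energy_conservation_and_determinism(head_pitch1, head_geometry):
    cfg = hp.SimulationConfig(n_packets=2000, seed=5)
    r1, f1, s1 = hp.run_simulation(head_pitch1, head_geometry["source"],
                                   head_geometry["detector"], cfg)
    assert s1.conservation_error < 1e-6
    r2, f2, s2 = hp.run_simulation(head_pitch1, head_geometry["source"],
                                   head_geometry["detector"], cfg)
    np.testing.assert_array_equal(f1.values, f2.values)
    np.testing.assert_array_equal(r1.weight, r2.weight)
    np.testing.assert_array_equal(r1.exit_time, r2.exit_time)
    assert s1.absorbed == s2.absorbed


def test_packet_time_invariant(head_pitch1, head_geometry):
    """exit_time equals sum(per-layer path * n)/c for every detected packet."""
    cfg = hp.SimulationConfig(n_packets=20000, seed=2)
    records, _, _ = hp.run_simulation(head_pitch1, head_geometry["source"],
                                      None, cfg)
    n_by_label = np.array([head_pitch1.layer_table[lab].n
                           for lab in records.labels])
    t = records.layer_path @ n_by_label / 299.792458
    np.testing.assert_allclose(records.exit_time, t, rtol=1e-9)
    # and the exit directions are unit vectors
    norms = np.linalg.norm(records.exit_direction, axis=1)
    np.testing.assert_allclose(norms, 1.0, atol=1e-9)


def test_similarity_relation_matched_mu_s_prime():
    """g=0 at mu_s' and g=0.9 at mu_s = mu_s'/0.1 transmit equal weight
    through a slab, within 3 MC standard errors (batch means)."""
    totals = []
    errs = []
    for g, mus in ((0.0, 1.0), (0.9, 10.0)):
        props = LayerOpticalProperties(1, "m", 0.01, mus, g, 1.0)
        slab = hp.build_slab_phantom(10.0, props, lateral_size=80.0,
                                     voxel_pitch=1.0, normal_axis=0)
        cy = slab.shape[1] * slab.voxel_pitch / 2
        src = hp.SourceSpec((slab.meta["entry_mm"], cy, cy), (1, 0, 0), diameter=0.0)
        batches = []
        for seed in range(8):
            cfg = hp.SimulationConfig(n_packets=4000, seed=seed,
                                      roulette_threshold=1e-8, max_time=50.0)
            records, _, _ = hp.run_simulation(slab, src, None, cfg)
            exit_x = records.exit_position[:, 0]
            transmitted = exit_x > slab.meta["exit_mm"] - 1e-6
            batches.append(records.weight[transmitted].sum() / 4000)
        batches = np.asarray(batches)
        totals.append(batches.mean())
        errs.append(batches.std(ddof=1) / np.sqrt(batches.size))
    diff = abs(totals[0] - totals[1])
    assert diff < 3 * np.hypot(errs[0], errs[1]), (totals, errs)


def test_fluence_profile_ballistic_beer_lambert():
    """On a purely absorbing slab the depth profile is exp(-mu_a z):
    the log-slope recovers mu_a within 2%."""
    mu_a = 0.05
    props = LayerOpticalProperties(1, "absorber", mu_a, 0.0, 0.0, 1.0)
    slab = hp.build_slab_phantom(60.0, props, lateral_size=30.0,
                                 voxel_pitch=1.0, normal_axis=0)
    cy = slab.shape[1] * slab.voxel_pitch / 2
    src = hp.SourceSpec((slab.meta["entry_mm"], cy, cy), (1, 0, 0), diameter=10.0)
    cfg = hp.SimulationConfig(n_packets=4000, seed=3, max_time=50.0)
    _, fluence, _ = hp.run_simulation(slab, src, None, cfg)
    profile = hp.fluence_depth_profile(fluence, slab, "x")
    assert profile.max() == 1.0
    z = np.flatnonzero(profile > 0)
    slope = np.polyfit(z[1:-1].astype(float), np.log(profile[z[1:-1]]), 1)[0]
    assert -slope == pytest.approx(mu_a, rel=0.02)


def test_fluence_profile_head_shape(head_transmission_run, head_pitch1):
    """Fluence-vs-depth on the head: normalized to max 1, rises only within
    the first ~10 mm (surface curvature), then decays monotonically after a
    5-slice mean smoothing over the statistically resolved shallow portion
    (10-60 mm; the deeper tail spans ~1e16 of attenuation and is noise at
    desk-scale packet counts)."""
    _, fluence, _ = head_transmission_run
    profile = hp.fluence_depth_profile(fluence, head_pitch1, "x")
    assert profile.max() == 1.0
    pitch = head_pitch1.voxel_pitch
    inside_x = np.flatnonzero(head_pitch1.inside_mask().any(axis=(1, 2)))
    start = inside_x[0] + int(round(10.0 / pitch))
    stop = inside_x[0] + int(round(60.0 / pitch))
    smoothed = np.convolve(profile, np.ones(5) / 5, mode="valid")
    assert np.argmax(profile) <= start
    assert np.all(np.diff(smoothed[start:stop]) <= 1e-12)


def test_csf_guiding_dominates_detected_weight(head_transmission_run):
    """Most detected weight crossed the CSF layer (light guided by CSF)."""
    records, _, _ = head_transmission_run
    assert len(records) >= 3
    csf_col = records.labels.index(3)
    w_csf = records.weight[records.layer_path[:, csf_col] > 0].sum()
    assert w_csf / records.weight.sum() > 0.5


def test_propagate_packet_errors(clear_cube):
    with pytest.raises(ValueError, match="outside the grid"):
        hp.propagate_packet((-5.0, 0.0, 0.0), (1, 0, 0), clear_cube)


def test_fluence_profile_axis_validation(head_pitch1):
    fl = hp.FluenceGrid(np.zeros(head_pitch1.shape), head_pitch1.voxel_pitch)
    with pytest.raises(ValueError):
        hp.fluence_depth_profile(fl, head_pitch1, "w")
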