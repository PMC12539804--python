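"""Superposition, helix axes, rotation/tilt between states, pore profiling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from twistgate import structure_metrics as sm
from twistgate import synthetic_data as sd
from twistgate.errors import DegenerateGeometryError


def _rot_z(deg):
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


# ---------------------------------------------------------------------------
# superposition


def test_superpose_identity(rng):
    pts = rng.normal(size=(10, 3))
    r, t, rmsd = sm.superpose(pts, pts)
    np.testing.assert_allclose(r, np.eye(3), atol=1e-10)
    np.testing.assert_allclose(t, 0.0, atol=1e-10)
    assert rmsd == pytest.approx(0.0, abs=1e-10)


def test_superpose_recovers_pure_rotation(rng):
    pts = rng.normal(size=(12, 3))
    r_true = _rot_z(30.0)
    mob = pts @ r_true.T
    r, t, rmsd = sm.superpose(pts, mob)
    np.testing.assert_allclose(r @ r_true, np.eye(3), atol=1e-9)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(r) == pytest.approx(1.0)


def test_superpose_noise_rmsd_bracket():
    hits = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        pts = r.normal(size=(30, 3))
        mob = pts + r.normal(0, 0.02, size=pts.shape)
        _, _, rmsd = sm.superpose(pts, mob)
        hits += 0.01 <= rmsd <= 0.04
    assert hits >= 19


def test_superpose_beats_random_rigid_transforms(rng):
    """Kabsch RMSD is minimal among arbitrary rigid alternatives."""
    pts = rng.normal(size=(15, 3))
    mob = pts @ _rot_z(25.0).T + np.array([0.3, -0.2, 0.5])
    mob = mob + rng.normal(0, 0.05, size=pts.shape)
    _, _, best = sm.superpose(pts, mob)
    for _ in range(25):
        r_alt = Rotation.random(random_state=rng).as_matrix()
        t_alt = rng.normal(size=3)
        alt = np.sqrt(np.mean(
            np.linalg.norm(mob @ r_alt.T + t_alt - pts, axis=1) ** 2))
        assert best <= alt + 1e-12


def test_superpose_degenerate_inputs():
    with pytest.raises(DegenerateGeometryError):
        sm.superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DegenerateGeometryError):
        sm.superpose(line, line)


# ---------------------------------------------------------------------------
# helix axes


def _ideal_helix(n=11, rise=0.15, direction=None):
    wind = sd._helix_offsets(n, 0.23)
    pts = np.column_stack([wind[:, 0], wind[:, 1], rise * np.arange(n)])
    if direction is not None:
        # rotate +z onto direction
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        rot, _ = Rotation.align_vectors(d[None], np.array([[0.0, 0.0, 1.0]]))
        pts = pts @ rot.as_matrix().T
    return pts


def test_helix_axis_of_z_built_helix():
    axis = sm.helix_axis(_ideal_helix())
    assert np.degrees(np.arccos(np.clip(axis @ [0, 0, 1.0], -1, 1))) < 1.0


def test_helix_axis_flips_with_residue_order():
    pts = _ideal_helix()
    np.testing.assert_allclose(sm.helix_axis(pts), -sm.helix_axis(pts[::-1]),
                               atol=1e-9)


def test_helix_axis_recovers_tilt_angle():
    tilt = 20.0
    d = [np.sin(np.deg2rad(tilt)), 0.0, np.cos(np.deg2rad(tilt))]
    axis = sm.helix_axis(_ideal_helix(direction=d))
    angle_from_z = np.degrees(np.arccos(np.clip(axis @ [0, 0, 1.0], -1, 1)))
    assert angle_from_z == pytest.approx(tilt, abs=0.5)


def test_helix_axis_needs_five_residues():
    with pytest.raises(DegenerateGeometryError):
        sm.helix_axis(np.zeros((4, 3)))


# ---------------------------------------------------------------------------
# rotation/tilt between states


def _pair(rotation=0.0, tilt=0.0, seed=0, rigid_motion=True):
    cfg = sd.GeneratorConfig(seed=seed, rotation_deg=rotation, tilt_deg=tilt)
    s1, s2, man = sd.make_helix_pair(cfg, rigid_motion=rigid_motion)
    split = man["n_scaffold"]
    return (s1.positions[split:], s2.positions[split:],
            s1.positions[:split], s2.positions[:split])


def test_identical_states_zero_angles():
    h1, _, sc1, _ = _pair()
    out = sm.rotation_tilt_angles(h1, h1, sc1, sc1)
    assert out.rotation_deg == pytest.approx(0.0, abs=1e-9)
    assert out.tilt_change_deg == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("rotation,tilt", [(15.0, 0.0), (-10.0, 0.0),
                                           (0.0, 8.0), (15.0, 8.0),
                                           (-15.0, 8.0)])
def test_rotation_tilt_signs_and_values(rotation, tilt):
    h1, h2, sc1, sc2 = _pair(rotation, tilt, seed=3)
    out = sm.rotation_tilt_angles(h1, h2, sc1, sc2)
    assert out.rotation_deg == pytest.approx(rotation, abs=0.5)
    assert out.tilt_change_deg == pytest.approx(tilt, abs=0.5)
    assert out.rmsd < 1e-6  # scaffold is rigid across states


def test_rotation_tilt_antisymmetric_under_state_swap():
    # both states in the membrane frame: the swapped comparison is only
    # meaningful when the reference state is membrane-aligned
    h1, h2, sc1, sc2 = _pair(12.0, 5.0, seed=4, rigid_motion=False)
    fwd = sm.rotation_tilt_angles(h1, h2, sc1, sc2)
    rev = sm.rotation_tilt_angles(h2, h1, sc2, sc1)
    assert rev.rotation_deg == pytest.approx(-fwd.rotation_deg, abs=1e-6)
    assert rev.tilt_change_deg == pytest.approx(-fwd.tilt_change_deg, abs=1e-6)


def test_rotation_tilt_invariant_to_global_motion(rng):
    h1, h2, sc1, sc2 = _pair(9.0, 3.0, seed=5)
    rot = Rotation.random(random_state=rng).as_matrix()
    shift = rng.normal(size=3)
    out0 = sm.rotation_tilt_angles(h1, h2, sc1, sc2)
    out1 = sm.rotation_tilt_angles(h1, h2 @ rot.T + shift,
                                   sc1, sc2 @ rot.T + shift)
    assert out1.rotation_deg == pytest.approx(out0.rotation_deg, abs=1e-6)
    assert out1.tilt_change_deg == pytest.approx(out0.tilt_change_deg, abs=1e-6)


def test_near_normal_helix_degenerate():
    h1, _, sc1, _ = _pair()
    vertical = np.column_stack(
        [np.zeros(11), np.zeros(11), 0.15 * np.arange(11)]
    )
    with pytest.raises(DegenerateGeometryError):
        sm.rotation_tilt_angles(vertical, vertical, sc1, sc1)


# ---------------------------------------------------------------------------
# pore profiling


def test_uniform_cylinder_radius(base_config):
    struct, _ = sd.make_pore(base_config, constriction=False)
    prof = sm.pore_radius_profile(
        struct.positions, z_window=(-2, 2), n_samples=9,
        vdw_radii=sm.vdw_radii_for(struct),
    )
    assert np.all(prof.defined)
    np.testing.assert_allclose(prof.radius, 0.35, atol=0.01)
    np.testing.assert_allclose(prof.center, 0.0, atol=0.01)


def test_constriction_located_at_correct_z(base_config):
    struct, manifest = sd.make_pore(base_config, constriction=True)
    prof = sm.pore_radius_profile(
        struct.positions, z_window=(-2, 2), n_samples=9,
        vdw_radii=sm.vdw_radii_for(struct),
    )
    r_min, z_min = prof.min_radius()
    assert r_min == pytest.approx(0.10, abs=0.01)
    assert z_min == pytest.approx(manifest["constriction_z"], abs=0.26)


def test_slices_outside_molecule_flagged_undefined(base_config):
    struct, _ = sd.make_pore(base_config)
    prof = sm.pore_radius_profile(
        struct.positions, z_window=(5.0, 8.0), n_samples=5,
        vdw_radii=sm.vdw_radii_for(struct),
    )
    assert not np.any(prof.defined)
    assert np.all(np.isnan(prof.radius))


def test_profile_invariant_to_rigid_motion_of_frame(base_config, rng):
    struct, _ = sd.make_pore(base_config)
    radii = sm.vdw_radii_for(struct)
    prof0 = sm.pore_radius_profile(struct.positions, z_window=(-2, 2),
                                   n_samples=9, vdw_radii=radii)
    shift = rng.normal(size=3)
    prof1 = sm.pore_radius_profile(struct.positions + shift, z_window=(-2, 2),
                                   n_samples=9, vdw_radii=radii,
                                   origin=shift)
    np.testing.assert_allclose(prof1.radius, prof0.radius, atol=1e-3)


def test_min_radius_series_static_pore_is_constant(base_config):
    struct, frames, _ = sd.make_dilating_pore(base_config, r_start=0.2,
                                              r_end=0.2, n_frames=3)
    out = sm.min_radius_series(frames, struct, gate_window=(-0.6, 0.6),
                               n_samples=7)
    vals = out.column("r_min")
    np.testing.assert_allclose(vals, vals[0], atol=1e-3)


def test_min_radius_series_dilating_gate_crosses_threshold(base_config):
    """Gate widening from 0.08 to 0.25 nm: the series increases
    monotonically and crosses the 0.2 nm opening threshold."""
    struct, frames, manifest = sd.make_dilating_pore(base_config,
                                                     n_frames=6)
    out = sm.min_radius_series(frames, struct, gate_window=(-0.6, 0.6),
                               n_samples=7)
    vals = out.column("r_min")
    assert np.all(np.diff(vals) > -1e-6)
    assert vals[0] < 0.2 < vals[-1]
    np.testing.assert_allclose(vals, manifest["gate_radius"], atol=0.01)
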