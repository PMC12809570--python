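import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memiso.geometry import (
    assign_leaflets,
    classify_all,
    classify_site,
    dihedral_angle,
    isomerize_all,
    isomerize_site,
    min_image_xy,
    unwrap_xy,
    wrap_xy,
)


def four_points_with_dihedral(angle_deg: float) -> np.ndarray:
    """Rotation-matrix construction of an exact torsion: start from the cis
    (0 deg) planar zig-zag and rotate p4 about the p2-p3 axis."""
    p1 = np.array([1.0, 1.0, 0.0])
    p2 = np.array([0.0, 0.0, 0.0])
    p3 = np.array([0.0, -1.5, 0.0])
    p4_cis = p3 + np.array([1.0, -1.0, 0.0])
    theta = np.radians(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])  # about -y = p2->p3 axis
    p4 = p3 + rot @ (p4_cis - p3)
    return np.array([p1, p2, p3, p4])


class TestDihedral:
    def test_cis_planar_zigzag_is_zero(self):
        pts = four_points_with_dihedral(0.0)
        assert dihedral_angle(*pts) == pytest.approx(0.0, abs=1e-10)

    def test_trans_planar_zigzag_is_180(self):
        pts = four_points_with_dihedral(180.0)
        assert abs(dihedral_angle(*pts)) == pytest.approx(180.0, abs=1e-9)

    def test_plus_90_rotation(self):
        pts = four_points_with_dihedral(90.0)
        assert abs(dihedral_angle(*pts)) == pytest.approx(90.0, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=-179.9, max_value=180.0))
    def test_rotation_construction_recovers_any_angle(self, angle):
        pts = four_points_with_dihedral(angle)
        assert abs(abs(dihedral_angle(*pts)) - abs(angle)) < 1e-8

    def test_result_in_half_open_range(self):
        pts = four_points_with_dihedral(-180.0)
        assert dihedral_angle(*pts) == pytest.approx(180.0)

    def test_degenerate_collinear_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            dihedral_angle([0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3])

    def test_coincident_points_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            dihedral_angle([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])


class TestClassify:
    @pytest.mark.parametrize(
        "angle,expected",
        [(3.0, "cis"), (-40.0, "cis"), (178.0, "trans"), (-120.0, "trans"),
         (90.0, "trans"), (89.9, "cis")],  # boundary rule: 90 deg -> trans
    )
    def test_threshold(self, angle, expected, tiny_built):
        traj, _ = tiny_built
        topo = traj.topology
        site = topo.sites[0]
        frame = traj.frame(0)
        frame.positions[list(site.dihedral_atom_indices)] = four_points_with_dihedral(angle)
        assert classify_site(frame, site) == expected


class TestIsomerize:
    def test_cis_becomes_trans(self, tiny_built):
        traj, _ = tiny_built
        frame = traj.frame(0)
        site = traj.topology.sites[0]
        assert classify_site(frame, site) == "cis"
        flipped = isomerize_site(frame, site, traj.topology)
        assert classify_site(flipped, site) == "trans"
        i1, i2, i3, i4 = site.dihedral_atom_indices
        d = dihedral_angle(*flipped.positions[[i1, i2, i3, i4]])
        assert abs(d) == pytest.approx(180.0, abs=1e-6)

    def test_involution_restores_coordinates(self, tiny_built):
        traj, _ = tiny_built
        frame = traj.frame(0)
        site = traj.topology.sites[0]
        twice = isomerize_site(isomerize_site(frame, site, traj.topology), site, traj.topology)
        assert np.abs(twice.positions - frame.positions).max() < 1e-6

    def test_isometry_on_distal_set_and_change_across(self, tiny_built):
        from memiso.geometry import _distal_set

        traj, _ = tiny_built
        frame = traj.frame(0)
        topo = traj.topology
        site = topo.sites[0]
        distal = _distal_set(topo, site)
        out = isomerize_site(frame, site, topo)
        d_in = frame.positions[distal][:, None, :] - frame.positions[distal][None, :, :]
        d_out = out.positions[distal][:, None, :] - out.positions[distal][None, :, :]
        assert np.abs(
            np.linalg.norm(d_in, axis=2) - np.linalg.norm(d_out, axis=2)
        ).max() < 1e-9
        # atoms outside the distal set are untouched ...
        others = np.setdiff1d(topo.residue_atoms(site.residue_index), distal)
        assert np.array_equal(out.positions[others], frame.positions[others])
        # ... so some cross-set distances must change (the chain bends)
        cross_in = np.linalg.norm(frame.positions[distal[-1]] - frame.positions[others[0]])
        cross_out = np.linalg.norm(out.positions[distal[-1]] - out.positions[others[0]])
        assert abs(cross_in - cross_out) > 1e-3

    def test_isomerize_all_flips_every_cis_site(self, tiny_built):
        traj, _ = tiny_built
        frame = traj.frame(0)
        topo = traj.topology
        out, rep = isomerize_all(frame, topo, target="trans")
        assert rep.n_flipped == len(topo.sites)
        assert set(rep.final_states) == {"trans"}

    def test_target_already_met_is_identity(self, tiny_built):
        traj, _ = tiny_built
        frame = traj.frame(0)
        out, rep = isomerize_all(frame, traj.topology, target="cis")
        assert rep.n_flipped == 0
        assert np.array_equal(out.positions, frame.positions)

    def test_mixed_membrane_selectivity(self, tiny_built):
        traj, _ = tiny_built
        topo = traj.topology
        frame = isomerize_site(traj.frame(0), topo.sites[0], topo)  # one trans site
        out, rep = isomerize_all(frame, topo, target="trans")
        assert rep.n_flipped == len(topo.sites) - 1
        assert set(classify_all(out, topo)) == {"trans"}


class TestLeaflets:
    def test_matches_generator_ground_truth(self, full_built_cis):
        traj, truth = full_built_cis
        labels = assign_leaflets(traj.frame(0), traj.topology, store=False)
        assert np.array_equal(labels, truth.leaflets)
        assert (labels == "upper").sum() == 50

    def test_translation_invariance(self, tiny_built):
        traj, truth = tiny_built
        frame = traj.frame(0)
        base = assign_leaflets(frame, traj.topology, store=False)
        frame.positions += np.array([13.0, -4.0, 7.0])
        moved = assign_leaflets(frame, traj.topology, store=False)
        assert np.array_equal(base, moved)


class TestPeriodicity:
    def test_min_image_halves(self):
        box = np.array([10.0, 20.0, 30.0])
        d = min_image_xy(np.array([[6.0, -11.0, 25.0]]), box)
        assert np.allclose(d, [[-4.0, 9.0, 25.0]])

    def test_wrap_into_box(self):
        box = np.array([10.0, 10.0, 10.0])
        assert np.allclose(wrap_xy(np.array([[12.0, -0.5, 3.0]]), box), [[2.0, 9.5, 3.0]])

    def test_single_boundary_crossing_continuous(self):
        boxes = np.tile([10.0, 10.0], (4, 1))
        x = np.array([8.0, 9.5, 0.5, 2.0])  # crosses +x once
        tracks = np.stack([x, np.full(4, 5.0)], axis=1)[:, None, :]
        un = unwrap_xy(tracks, boxes)
        assert np.allclose(np.diff(un[:, 0, 0]), [1.5, 1.0, 1.5])
        assert un[-1, 0, 0] - un[0, 0, 0] == pytest.approx(4.0)

    def test_stationary_particle_unchanged(self):
        tracks = np.full((5, 1, 2), 3.3)
        un = unwrap_xy(tracks, np.tile([10.0, 10.0], (5, 1)))
        assert np.array_equal(un, tracks)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_wrap_then_unwrap_recovers_brownian_track(self, seed):
        rng = np.random.default_rng(seed)
        box = np.array([12.0, 9.0])
        steps = rng.normal(0, 1.0, size=(200, 7, 2))  # step sd << box/2
        tracks = np.concatenate([rng.uniform(0, 9, (1, 7, 2)), np.cumsum(steps, axis=0)])
        tracks[1:] += tracks[:1]
        wrapped = tracks - box * np.floor(tracks / box)
        un = unwrap_xy(wrapped, np.tile(box, (201, 1)))
        # equal to the original up to the (integer-box) offset of frame 0
        assert np.allclose(un - un[:1], tracks - tracks[:1], atol=1e-9)
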