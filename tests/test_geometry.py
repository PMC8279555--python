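"""Chain building, internal-coordinate round trips, and geometric observables."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import chainfel as cf
from chainfel.geometry import (
    BONDI, VolumeEstimate, principal_frame, with_hydrogens,
)

ANGLES = st.floats(min_value=-179.999, max_value=180.0)


def random_rigid_motion(coords, seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    return coords @ rot.T + rng.uniform(-5, 5, size=3)


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------

class TestBuildCartesian:
    def test_single_bond(self):
        topo = cf.ChainTopology(2)
        coords = cf.build_cartesian(topo, [])
        assert coords.shape == (2, 3)
        assert np.linalg.norm(coords[1] - coords[0]) == pytest.approx(1.53)

    def test_all_trans_c11_matches_reported_extension(self, c11):
        conf = cf.Conformation(c11, np.full(8, 180.0))
        assert conf.r_ee == pytest.approx(12.6, abs=0.2)

    def test_bond_lengths_and_angles_exact(self):
        topo = cf.ChainTopology(9)
        coords = cf.build_cartesian(topo, [180, 60, -60, 170, -95, 30])
        bonds = np.diff(coords, axis=0)
        lengths = np.linalg.norm(bonds, axis=1)
        np.testing.assert_allclose(lengths, 1.53, atol=1e-9)
        cosang = [
            -np.dot(bonds[i], bonds[i + 1]) / (lengths[i] * lengths[i + 1])
            for i in range(len(bonds) - 1)
        ]
        np.testing.assert_allclose(
            np.rad2deg(np.arccos(cosang)), 112.7, atol=1e-9
        )

    def test_terminal_distance_matches_rotation_matrix_oracle(self):
        # independent oracle: propagate bond vectors with explicit rotations
        # (axis-angle about the local normal, then twist about the bond)
        l, theta = 1.53, np.deg2rad(112.7)
        phis = [180.0, 60.0]

        pts = [np.zeros(3), np.array([l, 0.0, 0.0])]
        pts.append(pts[1] + l * np.array([-np.cos(theta), np.sin(theta), 0.0]))
        for phi in phis:
            b1 = pts[-2] - pts[-3]
            b2 = pts[-1] - pts[-2]
            normal = np.cross(b1, b2)
            normal /= np.linalg.norm(normal)
            bend = Rotation.from_rotvec(-normal * (np.pi - theta))
            twist = Rotation.from_rotvec(
                (b2 / np.linalg.norm(b2)) * np.deg2rad(phi - 180.0)
            )
            new_bond = twist.apply(bend.apply(b2))
            pts.append(pts[-1] + new_bond)
        oracle_ree = np.linalg.norm(pts[-1] - pts[0])

        topo = cf.ChainTopology(5)
        built = cf.Conformation(topo, phis)
        assert built.r_ee == pytest.approx(oracle_ree, abs=1e-9)

    def test_wrong_dihedral_count_raises(self, c11):
        with pytest.raises(ValueError, match="dihedral"):
            cf.build_cartesian(c11, [180.0, 60.0])

    @given(st.lists(ANGLES, min_size=1, max_size=12))
    def test_round_trip_dihedrals(self, dihedrals):
        topo = cf.ChainTopology(len(dihedrals) + 3)
        coords = cf.build_cartesian(topo, dihedrals)
        measured = cf.measure_dihedrals(coords)
        expected = np.asarray(dihedrals)
        expected[expected <= -180.0] = 180.0
        np.testing.assert_allclose(measured, expected, atol=1e-6)

    @given(st.lists(ANGLES, min_size=1, max_size=10), st.integers(0, 100))
    def test_r_ee_never_exceeds_all_trans_length(self, dihedrals, seed):
        topo = cf.ChainTopology(len(dihedrals) + 3)
        conf = cf.Conformation(topo, dihedrals)
        assert conf.r_ee <= cf.all_trans_length(topo) + 1e-9


class TestEndToEnd:
    def test_pythagorean_pair(self):
        assert cf.end_to_end(np.array([[0, 0, 0], [3, 4, 0.0]])) == 5.0

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            cf.end_to_end(np.zeros((1, 3)))

    @given(st.lists(ANGLES, min_size=2, max_size=8), st.integers(0, 10))
    def test_rigid_motion_and_mirror_invariance(self, dihedrals, seed):
        topo = cf.ChainTopology(len(dihedrals) + 3)
        coords = cf.build_cartesian(topo, dihedrals)
        moved = random_rigid_motion(coords, seed)
        mirrored = coords * np.array([1.0, 1.0, -1.0])
        assert cf.end_to_end(moved) == pytest.approx(cf.end_to_end(coords), abs=1e-9)
        assert cf.end_to_end(mirrored) == pytest.approx(cf.end_to_end(coords), abs=1e-9)


class TestAllTransLength:
    def test_single_bond_collapses_to_bond_length(self):
        assert cf.all_trans_length(cf.ChainTopology(2)) == pytest.approx(1.53)

    @pytest.mark.parametrize("n", range(2, 31))
    def test_closed_form_equals_builder(self, n):
        topo = cf.ChainTopology(n)
        conf = cf.Conformation(topo, np.full(topo.n_dihedrals, 180.0))
        assert cf.all_trans_length(topo) == pytest.approx(conf.r_ee, abs=1e-9)


class TestDihedralClassification:
    @pytest.mark.parametrize("dihedrals, expected_fraction", [
        ([180.0] * 5, 0.0),
        ([60.0] * 4, 1.0),
        ([180, 60, -60, 170], 0.5),
    ])
    def test_gauche_fraction(self, dihedrals, expected_fraction):
        assert cf.gauche_fraction(dihedrals) == expected_fraction

    def test_labels_and_zero_tie_break(self):
        assert cf.classify_dihedrals([180, 60, -60, 0.0]) == ["t", "g+", "g-", "g+"]


class TestRmsEndToEnd:
    def test_single_conformation_is_identity(self, c11):
        conf = cf.Conformation(c11, np.full(8, 180.0))
        assert cf.rms_end_to_end([conf]) == pytest.approx(conf.r_ee)

    def test_two_equal_weights(self):
        assert cf.rms_end_to_end([3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cf.rms_end_to_end([3.0, 4.0], weights=[0.0, 0.0])


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def sphere_volume(r):
    return 4.0 / 3.0 * np.pi * r**3


def lens_volume(r1, r2, d):
    """Analytic sphere-sphere intersection volume."""
    return (
        np.pi * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )


class TestVdwVolume:
    def test_single_carbon_sphere(self):
        est = cf.vdw_volume(np.zeros((1, 3)), [1.70], n_points=200_000, seed=1)
        assert abs(est.value - sphere_volume(1.70)) < 3 * est.stderr

    def test_two_disjoint_spheres_additive(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        est = cf.vdw_volume(coords, [1.7, 1.2], n_points=400_000, seed=2)
        expected = sphere_volume(1.7) + sphere_volume(1.2)
        assert abs(est.value - expected) < 3 * est.stderr

    def test_two_overlapping_spheres_lens_corrected(self):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        est = cf.vdw_volume(coords, [1.7, 1.7], n_points=400_000, seed=3)
        expected = 2 * sphere_volume(1.7) - lens_volume(1.7, 1.7, 1.5)
        assert abs(est.value - expected) < 3 * est.stderr

    def test_reproducible_for_fixed_seed(self):
        coords = np.zeros((1, 3))
        a = cf.vdw_volume(coords, [1.7], n_points=100_000, seed=7)
        b = cf.vdw_volume(coords, [1.7], n_points=100_000, seed=7)
        assert a == b

    def test_convergence_rate(self):
        # standard error shrinks like 1/sqrt(n_points)
        coords = np.zeros((1, 3))
        e1 = cf.vdw_volume(coords, [1.7], n_points=100_000, seed=1)
        e2 = cf.vdw_volume(coords, [1.7], n_points=1_600_000, seed=1)
        assert e2.stderr == pytest.approx(e1.stderr / 4.0, rel=0.05)

    def test_rejects_empty_and_tiny_sampling(self):
        with pytest.raises(ValueError):
            cf.vdw_volume(np.zeros((0, 3)), [], n_points=200_000)
        with pytest.raises(ValueError):
            cf.vdw_volume(np.zeros((1, 3)), [1.7], n_points=10)


class TestHydrogens:
    def test_all_atom_counts_and_ch_lengths(self):
        topo = cf.ChainTopology(6, with_hydrogens=True)
        conf = cf.Conformation(topo, np.full(3, 180.0))
        elements, coords = with_hydrogens(topo, conf.coords)
        assert elements.count("C") == 6
        assert elements.count("H") == 14  # CnH2n+2
        h = coords[6:]
        dmin = np.min(
            np.linalg.norm(h[:, None, :] - conf.coords[None, :, :], axis=2),
            axis=1,
        )
        np.testing.assert_allclose(dmin, 1.09, atol=1e-9)


class TestPackingFraction:
    def test_identity(self):
        assert cf.packing_fraction(740.0, 740.0) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cf.packing_fraction(-1.0, 740.0)
        with pytest.raises(ValueError):
            cf.packing_fraction(350.0, 0.0)


class TestPrincipalFrame:
    def test_long_axis_mapped_to_z(self, c11):
        conf = cf.Conformation(c11, np.full(8, 180.0))
        aligned = principal_frame(conf.coords)
        extents = aligned.max(axis=0) - aligned.min(axis=0)
        assert np.argmax(extents) == 2
        assert np.allclose(aligned.mean(axis=0), 0.0, atol=1e-9)
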