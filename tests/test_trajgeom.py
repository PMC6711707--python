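"""Membrane-plane fitting, geometry descriptors and distributions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fcgrkit import trajgeom as tg
from fcgrkit.synthetic import SyntheticTrajectorySpec, build_toy_trajectory


def _frame(records):
    """records: list of (atom, resnum, resname, chain, (x, y, z))."""
    return tg.Frame(
        0,
        np.array([r[0] for r in records], dtype="U6"),
        np.array([r[1] for r in records], dtype=int),
        np.array([r[2] for r in records], dtype="U4"),
        np.array([r[3] for r in records], dtype="U2"),
        np.array([r[4] for r in records], dtype=float),
    )


def _rotation(axis, angle_deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


TOY_SPEC = SyntheticTrajectorySpec(
    tilt_deg=40.0, incl_deg=40.0, d_c1=30.0, span_s218_p221=11.0
)


def _descriptors(frame, plane):
    return np.array(
        [
            tg.helix_tilt_angle(frame, "A:222-248:CA", plane),
            tg.ectodomain_inclination(frame, plane),
            tg.domain_membrane_distance(frame, "A:50-80:CA", plane),
            tg.segment_normal_length(frame, 218, 221, plane),
        ]
    )


class TestMembranePlane:
    def test_flat_anchor_plane(self):
        recs = [("P", 1000 + i, "LIP", "M", (x, y, 0.0))
                for i, (x, y) in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)])]
        plane = tg.membrane_plane(_frame(recs), "M:*:P")
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert plane.offset == pytest.approx(0.0, abs=1e-12)

    def test_tilted_anchor_plane_recovers_rotation(self):
        rot = _rotation([1, 0, 0], 10.0)
        pts = np.array([(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0), (2, 1, 0)], float) @ rot.T
        recs = [("P", 1000 + i, "LIP", "M", p) for i, p in enumerate(pts)]
        plane = tg.membrane_plane(_frame(recs), "M:*:P")
        angle = math.degrees(math.acos(np.clip(plane.normal @ np.array([0, 0, 1.0]), -1, 1)))
        assert angle == pytest.approx(10.0, abs=1e-9)

    def test_too_few_or_collinear_anchors_rejected(self):
        two = [("P", 1, "LIP", "M", (0, 0, 0)), ("P", 2, "LIP", "M", (1, 0, 0))]
        with pytest.raises(ValueError):
            tg.membrane_plane(_frame(two), "M:*:P")
        col = [("P", i, "LIP", "M", (i, 0.0, 0.0)) for i in range(5)]
        with pytest.raises(ValueError):
            tg.membrane_plane(_frame(col), "M:*:P")


class TestTilt:
    def test_perpendicular_and_in_plane_helices(self):
        plane = tg.MembraneModel.fixed_z(0.0)
        vert = [("CA", 222 + i, "ALA", "A", (0, 0, 1.5 * i)) for i in range(8)]
        assert tg.helix_tilt_angle(_frame(vert), "A:*:CA", plane) == pytest.approx(90.0, abs=1e-9)
        flat = [("CA", 222 + i, "ALA", "A", (1.5 * i, 0, 5.0)) for i in range(8)]
        assert tg.helix_tilt_angle(_frame(flat), "A:*:CA", plane) == pytest.approx(0.0, abs=1e-9)

    def test_toy_trajectory_tilt_recovered_exactly(self):
        frame = build_toy_trajectory(TOY_SPEC)[0]
        plane = tg.membrane_plane(frame, "M:*:P")
        assert tg.helix_tilt_angle(frame, "A:222-248:CA", plane) == pytest.approx(40.0, abs=1e-6)

    def test_too_few_atoms_rejected(self):
        three = [("CA", 222 + i, "ALA", "A", (0, 0, 1.5 * i)) for i in range(3)]
        with pytest.raises(ValueError):
            tg.helix_tilt_angle(_frame(three), "A:*:CA", tg.MembraneModel.fixed_z())


class TestInclination:
    def test_straight_up_and_level_vectors(self):
        plane = tg.MembraneModel.fixed_z(0.0)
        up = [("CA", 223, "ALA", "A", (0, 0, 0)), ("CA", 131, "GLY", "A", (0, 0, 30))]
        assert tg.ectodomain_inclination(_frame(up), plane) == pytest.approx(90.0, abs=1e-9)
        level = [("CA", 223, "ALA", "A", (0, 0, 5)), ("CA", 131, "GLY", "A", (30, 0, 5))]
        assert tg.ectodomain_inclination(_frame(level), plane) == pytest.approx(0.0, abs=1e-9)

    def test_signed_below_plane(self):
        plane = tg.MembraneModel.fixed_z(0.0)
        down = [("CA", 223, "ALA", "A", (0, 0, 0)), ("CA", 131, "GLY", "A", (10, 0, -10))]
        assert tg.ectodomain_inclination(_frame(down), plane) == pytest.approx(-45.0, abs=1e-9)

    def test_toy_trajectory_inclination_recovered_exactly(self):
        frame = build_toy_trajectory(TOY_SPEC)[0]
        plane = tg.membrane_plane(frame, "M:*:P")
        assert tg.ectodomain_inclination(frame, plane) == pytest.approx(40.0, abs=1e-6)

    def test_missing_group_rejected(self):
        one = [("CA", 223, "ALA", "A", (0, 0, 0))]
        with pytest.raises(ValueError):
            tg.ectodomain_inclination(_frame(one), tg.MembraneModel.fixed_z())


class TestDomainDistance:
    def test_com_height_above_plane(self):
        recs = [("CA", 50, "GLY", "A", (0, 0, 30.0)), ("CA", 51, "GLY", "A", (5, 0, 30.0))]
        d = tg.domain_membrane_distance(_frame(recs), "A:*:CA", tg.MembraneModel.fixed_z(0.0))
        assert d == pytest.approx(30.0, abs=1e-12)

    def test_in_plane_translation_invariance(self):
        frame = build_toy_trajectory(TOY_SPEC)[0]
        plane = tg.membrane_plane(frame, "M:*:P")
        d0 = tg.domain_membrane_distance(frame, "A:50-80:CA", plane)
        moved = frame.transformed(np.eye(3), np.array([12.0, -7.0, 0.0]))
        plane2 = tg.membrane_plane(moved, "M:*:P")
        assert tg.domain_membrane_distance(moved, "A:50-80:CA", plane2) == pytest.approx(d0, abs=1e-9)

    def test_toy_trajectory_distance_recovered_exactly(self):
        frame = build_toy_trajectory(TOY_SPEC)[0]
        plane = tg.membrane_plane(frame, "M:*:P")
        assert tg.domain_membrane_distance(frame, "A:50-80:CA", plane) == pytest.approx(30.0, abs=1e-6)

    def test_unknown_element_warns_and_uses_unit_mass(self):
        recs = [("XX1", 50, "UNK", "A", (0, 0, 10.0)), ("XX2", 51, "UNK", "A", (0, 0, 20.0))]
        with pytest.warns(RuntimeWarning):
            d = tg.domain_membrane_distance(_frame(recs), "A:*", tg.MembraneModel.fixed_z())
        assert d == pytest.approx(15.0)

    def test_empty_selection_rejected(self):
        frame = build_toy_trajectory(TOY_SPEC)[0]
        with pytest.raises(ValueError):
            tg.domain_membrane_distance(frame, "Z:999:CA", tg.MembraneModel.fixed_z())


class TestSegmentSpan:
    def test_constructed_eleven_angstrom_span(self):
        recs = []
        for res, rname, z in ((218, "SER", 16.0), (221, "PRO", 5.0)):
            for atom in ("N", "CA", "C", "O"):
                recs.append((atom, res, rname, "A", (res * 0.1, 0.0, z)))
        span = tg.segment_normal_length(_frame(recs), 218, 221, tg.MembraneModel.fixed_z())
        assert span == pytest.approx(11.0, abs=1e-12)

    def test_equal_height_gives_zero(self):
        recs = []
        for res in (218, 221):
            for atom in ("N", "CA", "C", "O"):
                recs.append((atom, res, "SER", "A", (res * 0.1, 0.0, 5.0)))
        assert tg.segment_normal_length(_frame(recs), 218, 221, tg.MembraneModel.fixed_z()) == 0.0

    def test_missing_backbone_rejected(self):
        recs = [("N", 218, "SER", "A", (0, 0, 0)), ("CA", 221, "PRO", "A", (0, 0, 5))]
        with pytest.raises(ValueError):
            tg.segment_normal_length(_frame(recs), 218, 221, tg.MembraneModel.fixed_z())


class TestDihedrals:
    @staticmethod
    def _backbone_frame(coords):
        # C(216), N/CA/C(217), N(218)
        names = ["C", "N", "CA", "C", "N"]
        resn = [216, 217, 217, 217, 218]
        return _frame(
            [(names[i], resn[i], "PRO", "A", coords[i]) for i in range(5)]
        )

    def test_planar_trans_phi_is_180(self):
        coords = [(-2, 1, 0), (-1, 0, 0), (0, 1, 0), (1, 0, 0), (2, 1, 0)]
        phi, psi = tg.backbone_dihedrals(self._backbone_frame(coords), 217)
        assert abs(phi) == pytest.approx(180.0, abs=1e-9)
        assert abs(psi) == pytest.approx(180.0, abs=1e-9)

    def test_reference_quadruple_is_minus_ninety(self):
        # Brute-force vector algebra gives -90 deg for this quadruple.
        coords = [(1, 0, 0), (0, 0, 0), (0, 1, 0), (0, 1, 1), (0, 0, 2)]
        phi, _ = tg.backbone_dihedrals(self._backbone_frame(coords), 217)
        assert phi == pytest.approx(-90.0, abs=1e-9)

    def test_mirror_image_negates_angles(self, rng):
        coords = rng.normal(size=(5, 3)) * 2.0
        frame = self._backbone_frame(coords)
        phi, psi = tg.backbone_dihedrals(frame, 217)
        mirrored = self._backbone_frame(coords * np.array([1.0, 1.0, -1.0]))
        phi_m, psi_m = tg.backbone_dihedrals(mirrored, 217)
        assert phi_m == pytest.approx(-phi, abs=1e-9)
        assert psi_m == pytest.approx(-psi, abs=1e-9)

    def test_agrees_with_mdanalysis_convention(self, rng):
        mda = pytest.importorskip("MDAnalysis.lib.distances")
        for _ in range(10):
            p = rng.normal(size=(4, 3)) * 3.0
            ours = tg._dihedral(*p)
            ref = math.degrees(
                float(mda.calc_dihedrals(p[0][None], p[1][None], p[2][None], p[3][None])[0])
            )
            assert ours == pytest.approx(ref, abs=1e-4)  # reference is float32

    def test_chain_terminus_rejected(self):
        recs = [("N", 217, "PRO", "A", (0, 0, 0)), ("CA", 217, "PRO", "A", (1, 0, 0)),
                ("C", 217, "PRO", "A", (1, 1, 0))]
        with pytest.raises(ValueError):
            tg.backbone_dihedrals(_frame(recs), 217)


class TestPairDistance:
    def test_pythagorean_distance(self):
        recs = [("OG1", 232, "THR", "A", (0, 0, 0)), ("O", 228, "VAL", "A", (3, 4, 0))]
        r = tg.atom_pair_distance(_frame(recs), "A:232:OG1", "A:228:O")
        assert r.distance == pytest.approx(5.0, abs=1e-12)
        assert not r.is_hbond

    def test_coincident_atoms(self):
        recs = [("OG1", 232, "THR", "A", (1, 2, 3)), ("O", 228, "VAL", "A", (1, 2, 3))]
        r = tg.atom_pair_distance(_frame(recs), "A:232:OG1", "A:228:O")
        assert r.distance == 0.0 and r.is_hbond

    def test_hbond_threshold_and_nearest_candidate(self):
        recs = [("OG1", 232, "THR", "A", (0, 0, 0)),
                ("O", 228, "VAL", "A", (0, 0, 3.4)),
                ("O", 229, "ALA", "A", (0, 0, 8.0))]
        r = tg.atom_pair_distance(_frame(recs), "A:232:OG1", "A:228-229:O")
        assert r.distance == pytest.approx(3.4) and r.is_hbond
        r2 = tg.atom_pair_distance(_frame(recs), "A:232:OG1", "A:228-229:O", hbond_cutoff=3.0)
        assert not r2.is_hbond

    def test_missing_atom_rejected(self):
        recs = [("OG1", 232, "THR", "A", (0, 0, 0))]
        with pytest.raises(ValueError):
            tg.atom_pair_distance(_frame(recs), "A:232:OG1", "A:228:O")


class TestDistribution:
    def test_constant_series_single_bin(self):
        h = tg.probability_distribution([3.2] * 50, bin_width=0.5)
        assert h.probabilities.sum() == pytest.approx(1.0)
        assert np.max(h.probabilities) == 1.0

    def test_uniform_samples_flat_histogram(self, rng):
        v = rng.uniform(0, 10, size=20_000)
        h = tg.probability_distribution(v, bin_width=1.0)
        se = math.sqrt(0.1 * 0.9 / 20_000)
        np.testing.assert_allclose(h.probabilities, 0.1, atol=3 * se)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=200))
    def test_normalization_and_bin_count(self, values):
        h = tg.probability_distribution(values, bin_width=2.0)
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        span = max(values) - min(values)
        assert len(h.probabilities) <= math.ceil(span / 2.0) + 1

    def test_edges_aligned_and_mode(self):
        h = tg.probability_distribution([1.1, 1.2, 1.3, 7.9], bin_width=2.0)
        assert h.edges[0] == 0.0 and h.edges[-1] == 8.0
        assert h.mode == 1.0  # centre of [0, 2)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            tg.probability_distribution([], bin_width=1.0)


class TestRoundTripAndInvariance:
    def test_jitter_free_spec_recovered_to_numerical_precision(self):
        frame = build_toy_trajectory(TOY_SPEC)[0]
        plane = tg.membrane_plane(frame, "M:*:P")
        np.testing.assert_allclose(_descriptors(frame, plane), [40.0, 40.0, 30.0, 11.0], atol=1e-6)

    def test_rigid_transform_invariance(self, rng):
        # The plane normal is oriented by the ectodomain side so signed
        # descriptors survive arbitrary rotation of the whole frame.
        frame = build_toy_trajectory(TOY_SPEC)[0]
        plane = tg.membrane_plane(frame, "M:*:P", orient_toward="A:130-132")
        ref = _descriptors(frame, plane)
        for _ in range(20):
            rot = _random_rotation(rng)
            shift = rng.normal(scale=25.0, size=3)
            moved = frame.transformed(rot, shift)
            plane_m = tg.membrane_plane(moved, "M:*:P", orient_toward="A:130-132")
            np.testing.assert_allclose(_descriptors(moved, plane_m), ref, atol=1e-6)

    def test_descriptor_series_over_frames(self):
        spec = SyntheticTrajectorySpec(
            tilt_deg=40, incl_deg=40, d_c1=30, span_s218_p221=11,
            n_frames=25, jitter_sd=0.3, seed=4,
        )
        frames = build_toy_trajectory(spec)
        series = tg.compute_series(
            frames,
            lambda f: tg.helix_tilt_angle(f, "A:222-248:CA", tg.membrane_plane(f, "M:*:P")),
            "tm_tilt", "deg",
        )
        assert len(series.values) == 25
        summary = series.summary()
        assert 35.0 < summary["mean"] < 45.0 and summary["sd"] > 0
        h = series.histogram(bin_width=2.0)
        assert h.probabilities.sum() == pytest.approx(1.0)


class TestIO:
    def test_csv_round_trip_exact(self, tmp_path):
        frames = build_toy_trajectory(
            SyntheticTrajectorySpec(n_frames=3, jitter_sd=0.2, seed=1)
        )
        path = tmp_path / "traj.csv"
        tg.write_trajectory(frames, path)
        back = tg.read_trajectory(path)
        assert len(back) == 3
        for a, b in zip(frames, back):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-12)
            np.testing.assert_array_equal(a.res_num, b.res_num)

    def test_multi_model_pdb_round_trip(self, tmp_path):
        frames = build_toy_trajectory(SyntheticTrajectorySpec(n_frames=2))
        path = tmp_path / "traj.pdb"
        tg.write_trajectory(frames, path)
        back = tg.read_trajectory(str(path))
        assert len(back) == 2
        # PDB stores 1e-3 A precision; descriptors must survive to ~1e-2.
        plane = tg.membrane_plane(back[0], "M:*:P")
        np.testing.assert_allclose(
            _descriptors(back[0], plane), [40.0, 40.0, 30.0, 11.0], atol=1e-2
        )
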