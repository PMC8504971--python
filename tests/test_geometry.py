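"""Tilt/rotation axes, TM inclination, superposition and RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tcrtilt.geometry import (
    GeometryError,
    ca_rmsd,
    center_of_mass,
    helix_inclination,
    orient_reference_by_tm,
    orientation,
    superpose,
    tcr_axes,
)
from tcrtilt.structure_io import Ensemble, Span
from tcrtilt.synthetic import build_frame

from conftest import make_conformation


def _rotation_about_z(deg):
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


class TestCenterOfMass:
    def test_equal_masses_midpoint(self):
        conf = make_conformation([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("A", 2, "ALA", "CA", "C", (0, 0, 2)),
        ])
        np.testing.assert_allclose(
            center_of_mass(conf, ("A", (1, 2))), [0, 0, 1]
        )

    def test_single_atom_identity(self):
        conf = make_conformation([("A", 1, "ALA", "CA", "C", (1.0, 2.0, 3.0))])
        np.testing.assert_allclose(center_of_mass(conf, ("A", (1, 1))), [1, 2, 3])

    def test_mass_weighting_carbon_oxygen(self):
        # oracle: explicit weighted sum with masses 12.011 and 15.999
        conf = make_conformation([
            ("A", 1, "ALA", "C", "C", (0, 0, 0)),
            ("A", 1, "ALA", "O", "O", (0, 0, 2.8)),
        ])
        expected_z = 15.999 / (12.011 + 15.999) * 2.8
        np.testing.assert_allclose(
            center_of_mass(conf, ("A", (1, 1))), [0, 0, expected_z], atol=1e-12
        )

    def test_empty_selection_raises(self):
        conf = make_conformation([("A", 1, "ALA", "CA", "C", (0, 0, 0))])
        with pytest.raises(GeometryError, match="no atoms"):
            center_of_mass(conf, ("B", (1, 1)))

    def test_hydrogen_switch(self):
        conf = make_conformation([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("A", 1, "ALA", "HA", "H", (0, 0, 1)),
        ])
        with_h = center_of_mass(conf, ("A", (1, 1)))[2]
        heavy = center_of_mass(conf, ("A", (1, 1)), include_hydrogens=False)[2]
        assert heavy == 0.0 and with_h > 0.0


class TestTcrAxes:
    def _four_domain_conf(self, va, vb, ca, cb):
        atoms = []
        for (chain, r0), pos in (("A", 1, ), va), (("B", 1), vb), (("A", 10), ca), (("B", 10), cb):
            for k in range(4):
                off = np.zeros(3)
                off[k % 3] = 0.05 * (1 if k < 3 else -1)
                atoms.append((chain, r0 + k, "ALA", "CA", "C", np.asarray(pos) + off))
        return make_conformation(atoms)

    def test_vertical_axis_a(self, toy_domain_map):
        conf = self._four_domain_conf(
            va=(-1, 0, 4), vb=(1, 0, 4), ca=(-1, 0, 0), cb=(1, 0, 0)
        )
        a, b = tcr_axes(conf, toy_domain_map)
        np.testing.assert_allclose(a, [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(b, [1, 0, 0], atol=1e-9)

    def test_degenerate_axis_b(self, toy_domain_map):
        conf = self._four_domain_conf(
            va=(0, 0, 4), vb=(0, 0, 4), ca=(-1, 0, 0), cb=(1, 0, 0)
        )
        with pytest.raises(GeometryError, match="degenerate"):
            tcr_axes(conf, toy_domain_map)


class TestOrientation:
    def test_grid_round_trip(self, dm):
        """Synthetic frames at prescribed angles are recovered to 1e-4 deg."""
        incl = {k: 15.0 for k in dm.tm_helices}
        for tilt in (15.0, 35.0, 55.0):
            for rot in (0.0, 25.0, 55.0, -40.0):
                conf = build_frame(dm, tilt, rot, incl)
                rec = orientation(conf, dm)
                assert rec.tilt == pytest.approx(tilt, abs=1e-4)
                assert rec.rotation == pytest.approx(rot, abs=1e-4)

    def test_tilt_zero_rotation_undefined(self, dm):
        conf = build_frame(dm, 0.0, 0.0, {k: 15.0 for k in dm.tm_helices})
        rec = orientation(conf, dm)
        assert rec.tilt == pytest.approx(0.0, abs=1e-6)
        assert np.isnan(rec.rotation)

    def test_invariance_under_z_rotation(self, dm):
        """Tilt/rotation must not change when the frame spins about z."""
        incl = {k: 15.0 for k in dm.tm_helices}
        conf = build_frame(dm, 33.0, 20.0, incl)
        rng = np.random.default_rng(7)
        for _ in range(5):
            rot_z = _rotation_about_z(rng.uniform(0, 360))
            rec = orientation(conf.transformed(rotation=rot_z), dm)
            assert rec.tilt == pytest.approx(33.0, abs=1e-6)
            assert rec.rotation == pytest.approx(20.0, abs=1e-6)

    def test_sign_flip_under_va_vb_swap(self, dm):
        """Swapping the Valpha/Vbeta labels flips the rotation sign only."""
        conf = build_frame(dm, 33.0, 20.0, {k: 15.0 for k in dm.tm_helices})
        swapped = dm.__class__(
            domains={**dm.domains,
                     "Valpha": dm.domains["Vbeta"],
                     "Vbeta": dm.domains["Valpha"]},
            tm_helices=dm.tm_helices, elements={}, dimers=dm.dimers,
        )
        rec = orientation(conf, dm)
        rec_swapped = orientation(conf, swapped)
        assert rec_swapped.tilt == pytest.approx(rec.tilt, abs=1e-9)
        assert rec_swapped.rotation == pytest.approx(-rec.rotation, abs=1e-6)

    def test_inter_axis_invariant_under_rigid_motion(self, dm):
        conf = build_frame(dm, 40.0, 30.0, {k: 15.0 for k in dm.tm_helices})
        ref = orientation(conf, dm).inter_axis_angle
        rot = Rotation.from_euler("xyz", [31, -17, 101], degrees=True).as_matrix()
        moved = conf.transformed(rotation=rot, translation=(1.0, -2.0, 3.0))
        assert orientation(moved, dm).inter_axis_angle == pytest.approx(ref, abs=1e-6)


class TestHelixInclination:
    def _helix(self, axis, n=10):
        axis = np.asarray(axis, float)
        axis /= np.linalg.norm(axis)
        s = np.linspace(-0.8, 0.8, n)
        return make_conformation([
            ("A", 20 + i, "ALA", "CA", "C", s[i] * axis) for i in range(n)
        ])

    def test_vertical_helix_zero(self):
        conf = self._helix([0, 0, 1])
        assert helix_inclination(conf, Span("A", 20, 29)) == pytest.approx(0.0, abs=1e-9)

    def test_rotated_helix_reports_rotation_angle(self):
        """Rigidly rotating a vertical helix by 20 deg gives 20 deg."""
        rot = Rotation.from_euler("y", 20, degrees=True).as_matrix()
        conf = self._helix([0, 0, 1]).transformed(rotation=rot)
        assert helix_inclination(conf, Span("A", 20, 29)) == pytest.approx(20.0, abs=1e-6)

    def test_odd_residue_count_deterministic(self):
        conf = self._helix([1, 0, 3], n=27)
        v1 = helix_inclination(conf, Span("A", 20, 46))
        v2 = helix_inclination(conf, Span("A", 20, 46))
        assert v1 == v2
        assert 0.0 <= v1 <= 90.0

    def test_one_residue_span_raises(self):
        conf = self._helix([0, 0, 1])
        with pytest.raises(GeometryError, match="two residues"):
            helix_inclination(conf, Span("A", 20, 20))

    def test_fold_to_upper_quadrant(self):
        # a helix pointing mostly downward still reports <= 90 deg
        conf = self._helix([0.2, 0, -1])
        assert helix_inclination(conf, Span("A", 20, 29)) < 90.0


class TestSuperpose:
    def test_identical_structures(self, dm):
        conf = build_frame(dm, 30.0, 10.0, {k: 15.0 for k in dm.tm_helices})
        rot, t, rmsd = superpose(conf, conf, ["Valpha", "Vbeta"], dm)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0, atol=1e-9)

    def test_translation_recovered(self, dm):
        conf = build_frame(dm, 30.0, 10.0, {k: 15.0 for k in dm.tm_helices})
        moved = conf.transformed(translation=(1.0, 2.0, 3.0))
        rot, t, rmsd = superpose(moved, conf, ["Valpha"], dm)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(t, [-1, -2, -3], atol=1e-8)

    def test_noise_level_recovered(self, dm):
        """With sigma = 0.1 A noise the fit RMSD sits at the noise level."""
        rng = np.random.default_rng(3)
        conf = build_frame(dm, 30.0, 10.0, {k: 15.0 for k in dm.tm_helices})
        rot_true = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        moved = conf.transformed(rotation=rot_true, translation=(0.5, 0.5, 0.5))
        sigma_nm = 0.01  # 0.1 A
        moved.positions = moved.positions + rng.normal(0, sigma_nm, moved.positions.shape)
        _, _, rmsd = superpose(moved, conf,
                               ["Valpha", "Vbeta", "Calpha", "Cbeta"], dm)
        expected = np.sqrt(3) * 0.1  # A; 3 coordinates each with sigma
        assert rmsd == pytest.approx(expected, rel=0.25)

    def test_too_few_atoms(self, toy_domain_map):
        conf = make_conformation([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("A", 2, "ALA", "CA", "C", (1, 0, 0)),
        ])
        with pytest.raises(GeometryError, match="3 paired"):
            superpose(conf, conf, ("A", (1, 2)))

    def test_correspondence_mismatch_listed(self, toy_domain_map):
        c1 = make_conformation([
            ("A", i, "ALA", "CA", "C", (i, 0, 0)) for i in range(1, 5)
        ])
        c2 = make_conformation([
            ("A", i, "ALA", "CA", "C", (i, 0, 0)) for i in range(2, 6)
        ])
        with pytest.raises(GeometryError, match="mismatch"):
            superpose(c1, c2, ("A", (1, 5)))


class TestCaRmsd:
    def test_reference_vs_itself_zero(self, dm):
        conf = build_frame(dm, 30.0, 10.0, {k: 15.0 for k in dm.tm_helices})
        series = ca_rmsd(Ensemble([conf, conf]), conf, ["Valpha", "Vbeta"], dm)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_isotropic_noise_gives_sqrt3_sigma(self, dm):
        """Monte-Carlo oracle: isotropic sigma per coordinate gives an
        expected per-atom displacement of sigma*sqrt(3); the rigid fit only
        absorbs 6 DOF over ~400 atoms, a negligible correction."""
        rng = np.random.default_rng(11)
        ref = build_frame(dm, 30.0, 10.0, {k: 15.0 for k in dm.tm_helices})
        sigma_nm = 0.02
        frames = []
        for _ in range(20):
            f = ref.transformed(translation=(0, 0, 0))
            f.positions = f.positions + rng.normal(0, sigma_nm, f.positions.shape)
            frames.append(f)
        series = ca_rmsd(Ensemble(frames), ref,
                         ["Valpha", "Vbeta", "Calpha", "Cbeta"], dm)
        expected_a = np.sqrt(3) * sigma_nm * 10
        assert series.mean() == pytest.approx(expected_a, rel=0.10)


class TestOrientReferenceByTm:
    def test_rigid_copy_recovers_frame_orientation(self, dm):
        """A displaced rigid copy aligned via its TM helices reproduces the
        orientation of every target frame it is aligned to."""
        incl = {k: 15.0 for k in dm.tm_helices}
        targets = [build_frame(dm, t, r, incl) for t, r in [(31.0, 14.0), (40.0, 30.0)]]
        rot = Rotation.from_euler("xyz", [40, -60, 20], degrees=True).as_matrix()
        reference = targets[0].transformed(rotation=rot, translation=(3, -1, 2))
        records = orient_reference_by_tm(reference, Ensemble(targets), dm)
        # the TM anchors are identical across frames here, so the embedded
        # reference keeps its own EC orientation (31, 14) in every frame
        for rec in records:
            assert rec.tilt == pytest.approx(31.0, abs=1e-5)
            assert rec.rotation == pytest.approx(14.0, abs=1e-5)
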