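"""Backbone dihedrals, superposition, screw decomposition, helix axes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hdxconf as hc
from hdxconf.chainbuild import build_backbone
from hdxconf.geometry import dihedral_angle, screw_compose, wrap_angle
from hdxconf.structure import ResidueSelection


def brute_force_torsion(p0, p1, p2, p3):
    """Independent torsion implementation: project bond vectors onto the
    plane normal to the central bond and take the signed angle."""
    p0, p1, p2, p3 = map(np.asarray, (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    u = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = u @ w
    y = np.cross(b1n, u) @ w
    return np.degrees(np.arctan2(y, x))


class TestDihedrals:
    def test_matches_brute_force_on_random_points(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(4, 3))
            assert dihedral_angle(*pts) == pytest.approx(brute_force_torsion(*pts), abs=1e-9)

    def test_ideal_helix_recovered_to_machine_precision(self):
        st_ = build_backbone(np.full(8, -57.0), np.full(8, -47.0))
        d = hc.compute_dihedrals(st_)
        assert d["phi"].iloc[1:].to_numpy() == pytest.approx(-57.0, abs=1e-6)
        assert d["psi"].iloc[:-1].to_numpy() == pytest.approx(-47.0, abs=1e-6)

    def test_termini_are_flagged_undefined_not_zero(self):
        d = hc.compute_dihedrals(build_backbone(np.full(5, -60.0), np.full(5, -40.0)))
        assert np.isnan(d["phi"].iloc[0]) and not d["phi_defined"].iloc[0]
        assert np.isnan(d["psi"].iloc[-1]) and not d["psi_defined"].iloc[-1]

    def test_mirror_image_negates_dihedrals(self):
        a = build_backbone(np.full(6, -57.0), np.full(6, -47.0))
        mirrored = hc.StructureModel(a.atoms.assign(z=-a.atoms["z"]))
        da, dm = hc.compute_dihedrals(a), hc.compute_dihedrals(mirrored)
        mask = da["phi_defined"]
        assert dm.loc[mask, "phi"].to_numpy() == pytest.approx(
            -da.loc[mask, "phi"].to_numpy(), abs=1e-9)

    def test_difference_wraps_across_180(self):
        idx = pd.MultiIndex.from_tuples([("A", 1)], names=["chain", "resnum"])
        mk = lambda phi: pd.DataFrame({"phi": [phi], "psi": [0.0],
                                       "phi_defined": [True], "psi_defined": [True]}, index=idx)
        diff = hc.dihedral_difference(mk(170.0), mk(-170.0))
        assert diff["dphi"].iloc[0] == pytest.approx(20.0)

    def test_difference_symmetric_and_bounded(self, rng):
        idx = pd.MultiIndex.from_tuples([("A", i) for i in range(20)],
                                        names=["chain", "resnum"])
        mk = lambda v: pd.DataFrame({"phi": v[:, 0], "psi": v[:, 1],
                                     "phi_defined": True, "psi_defined": True}, index=idx)
        a, b = mk(rng.uniform(-180, 180, (20, 2))), mk(rng.uniform(-180, 180, (20, 2)))
        d1, d2 = hc.dihedral_difference(a, b), hc.dihedral_difference(b, a)
        assert np.allclose(d1["dphi"], d2["dphi"])
        assert ((d1[["dphi", "dpsi"]] >= 0) & (d1[["dphi", "dpsi"]] <= 180)).all().all()

    def test_key_mismatch_lists_offenders(self):
        idx1 = pd.MultiIndex.from_tuples([("A", 1)], names=["chain", "resnum"])
        idx2 = pd.MultiIndex.from_tuples([("A", 2)], names=["chain", "resnum"])
        mk = lambda idx: pd.DataFrame({"phi": [0.0], "psi": [0.0],
                                       "phi_defined": [True], "psi_defined": [True]}, index=idx)
        with pytest.raises(ValueError, match=r"\('A', 2\)"):
            hc.dihedral_difference(mk(idx1), mk(idx2))


class TestSuperpose:
    def test_self_superposition_is_identity(self, hinge_pair):
        a, _, _ = hinge_pair
        sel = ResidueSelection((("A", 1, 24),))
        tr, rmsd, n = hc.superpose(a, a, sel)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)
        assert n == 24

    def test_known_transform_recovered_within_1e9(self, hinge_pair, rng):
        a, _, _ = hinge_pair
        true = screw_compose(rng.normal(size=3), 73.0, pitch=2.0,
                             point=rng.normal(size=3))
        moved = a.transformed(true.rotation, true.translation)
        sel = ResidueSelection((("A", 1, 24),))
        tr, rmsd, _ = hc.superpose(a, moved, sel)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tr.rotation, true.rotation, atol=1e-9)
        assert np.allclose(tr.translation, true.translation, atol=1e-9)

    def test_forward_and_reverse_are_inverse_with_equal_rmsd(self, hinge_pair):
        a, b, _ = hinge_pair
        sel = ResidueSelection((("A", 1, 24),))
        t_ab, r_ab, _ = hc.superpose(a, b, sel)
        t_ba, r_ba, _ = hc.superpose(b, a, sel)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        comp = t_ab.compose(t_ba)
        assert np.allclose(comp.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(comp.translation, 0, atol=1e-8)

    def test_rmsd_invariant_under_common_rigid_motion(self, hinge_pair, rng):
        a, b, _ = hinge_pair
        sel = ResidueSelection((("A", 1, 24),))
        _, r0, _ = hc.superpose(a, b, sel)
        common = screw_compose(rng.normal(size=3), 40.0, point=rng.normal(size=3))
        _, r1, _ = hc.superpose(a.transformed(common.rotation, common.translation),
                                b.transformed(common.rotation, common.translation), sel)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_too_few_atoms_rejected(self, hinge_pair):
        a, b, _ = hinge_pair
        with pytest.raises(ValueError, match="3 paired atoms"):
            hc.superpose(a, b, ResidueSelection((("A", 1, 2),)))

    def test_never_returns_a_reflection(self, rng, make_structure):
        # a near-planar point set invites the reflected SVD solution
        pts = rng.normal(size=(6, 3)) * np.array([5.0, 5.0, 1e-4])
        a = make_structure(pts)
        b = make_structure(pts * np.array([1.0, 1.0, -1.0]))
        sel = ResidueSelection((("A", 1, 6),))
        tr, _, _ = hc.superpose(a, b, sel)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)


class TestScrew:
    def test_quarter_turn_about_z(self):
        s = hc.screw_decompose(screw_compose((0, 0, 1), 90.0))
        assert s.angle == pytest.approx(90.0, abs=1e-9)
        assert np.allclose(s.axis, [0, 0, 1], atol=1e-12)
        assert s.pitch == pytest.approx(0.0, abs=1e-12)

    def test_identity_is_pure_translation(self):
        s = hc.screw_decompose(hc.RigidTransform(np.eye(3), [1.0, 2.0, 2.0]))
        assert s.is_pure_translation
        assert s.axis is None
        assert s.pitch == pytest.approx(3.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(angle=st.floats(1.0, 179.0), pitch=st.floats(-5, 5),
           ax=st.tuples(*[st.floats(-1, 1)] * 3).filter(lambda v: np.linalg.norm(v) > 0.1))
    def test_compose_then_decompose_roundtrip(self, angle, pitch, ax):
        s = hc.screw_decompose(screw_compose(ax, angle, pitch, point=(1.0, -2.0, 0.5)))
        assert s.angle == pytest.approx(angle, abs=1e-7)
        assert s.pitch == pytest.approx(pitch, abs=1e-7)
        assert abs(s.axis @ (np.array(ax) / np.linalg.norm(ax))) == pytest.approx(1.0, abs=1e-9)

    def test_axis_point_is_fixed_in_the_normal_plane(self):
        t = screw_compose((0, 0, 1), 35.0, pitch=1.5, point=(3.0, 4.0, 0.0))
        s = hc.screw_decompose(t)
        moved = t.apply(s.point)
        assert np.allclose(moved - s.point, s.pitch * s.axis, atol=1e-9)

    def test_toy_hinge_transform_recovers_truth(self, hinge_pair):
        a, b, truth = hinge_pair
        n = truth.params["n_res_per_helix"]
        sel = ResidueSelection((("A", n + 1, 2 * n),))
        tr, rmsd, _ = hc.superpose(a, b, sel)
        s = hc.screw_decompose(tr)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert s.angle == pytest.approx(truth.params["hinge_angle"], abs=1e-6)
        assert np.allclose(s.axis, truth.params["hinge_axis"], atol=1e-6)

    def test_dihedral_change_confined_to_pivot(self, hinge_pair):
        a, b, truth = hinge_pair
        n = truth.params["n_res_per_helix"]
        diff = hc.dihedral_difference(hc.compute_dihedrals(a), hc.compute_dihedrals(b))
        nz = diff[(diff["dphi"] > 1e-9) | (diff["dpsi"] > 1e-9)]
        assert set(nz.index.get_level_values("resnum")) <= {n, n + 1}
        assert len(nz) > 0

    def test_zero_hinge_angle_gives_identical_structures(self):
        a, b, _ = hc.make_toy_hinge_structures(8, 0.0, (0, 0, 1))
        assert np.allclose(a.coords, b.coords)
        diff = hc.dihedral_difference(hc.compute_dihedrals(a), hc.compute_dihedrals(b))
        assert np.nanmax(diff[["dphi", "dpsi"]].to_numpy()) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            hc.make_toy_hinge_structures(8, 25.0, (0, 0, 0))


class TestHelixAxis:
    def test_parallel_helices_have_zero_angle(self):
        a = build_backbone(np.full(10, -57.0), np.full(10, -47.0))
        shifted = a.transformed(np.eye(3), np.array([30.0, 0.0, 0.0]))
        sel = ResidueSelection((("A", 1, 10),))
        acute, oriented = hc.inter_helix_angle(hc.helix_axis(a, sel),
                                               hc.helix_axis(shifted, sel))
        # arccos amplifies float rounding of the dot product to ~1e-6 deg
        assert acute == pytest.approx(0.0, abs=1e-4)
        assert oriented == pytest.approx(0.0, abs=1e-4)

    def test_orthogonal_helices_near_ninety(self):
        a = build_backbone(np.full(12, -57.0), np.full(12, -47.0))
        ax = hc.helix_axis(a, ResidueSelection((("A", 1, 12),)))
        # rotate a copy by 90 degrees about a vector orthogonal to its own axis
        perp = np.cross(ax.direction, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        t = screw_compose(perp, 90.0)
        b = a.transformed(t.rotation, t.translation)
        acute, _ = hc.inter_helix_angle(ax, hc.helix_axis(b, ResidueSelection((("A", 1, 12),))))
        assert acute == pytest.approx(90.0, abs=1.0)

    def test_antiparallel_is_oriented_180_but_acute_0(self):
        a = build_backbone(np.full(10, -57.0), np.full(10, -47.0))
        ax = hc.helix_axis(a, ResidueSelection((("A", 1, 10),)))
        flipped = hc.HelixAxis(-ax.direction, ax.centroid, ax.n_atoms)
        acute, oriented = hc.inter_helix_angle(ax, flipped)
        assert oriented == pytest.approx(180.0, abs=1e-4)
        assert acute == pytest.approx(0.0, abs=1e-4)

    def test_too_few_atoms_rejected(self):
        a = build_backbone(np.full(6, -57.0), np.full(6, -47.0))
        with pytest.raises(ValueError, match=">= 5 CA"):
            hc.helix_axis(a, ResidueSelection((("A", 1, 4),)))


class TestSiteDisplacement:
    def test_identical_structures_give_zero(self, hinge_pair):
        a, _, _ = hinge_pair
        sel = ResidueSelection((("A", 1, 12),))
        site = ResidueSelection((("A", 15, 18),))
        total, along = hc.site_displacement(a, a, sel, site, normal=(0, 0, 1))
        assert total == pytest.approx(0.0, abs=1e-12)
        assert along == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_along_supplied_normal(self, hinge_pair):
        a, _, _ = hinge_pair
        df = a.atoms.copy()
        moved = (df["resnum"] >= 15) & (df["resnum"] <= 18)
        df.loc[moved, "z"] += 5.0
        b = hc.StructureModel(df)
        total, along = hc.site_displacement(a, b, ResidueSelection((("A", 1, 12),)),
                                            ResidueSelection((("A", 15, 18),)),
                                            normal=(0, 0, 1))
        assert total == pytest.approx(5.0, abs=1e-9)
        assert along == pytest.approx(5.0, abs=1e-9)

    def test_auto_normal_requires_a_dimer(self, hinge_pair):
        a, b, _ = hinge_pair
        with pytest.raises(ValueError, match="single-chain"):
            hc.site_displacement(a, b, ResidueSelection((("A", 1, 12),)),
                                 ResidueSelection((("A", 15, 18),)), normal="auto")


def test_wrap_angle_convention():
    assert wrap_angle(190.0) == pytest.approx(-170.0)
    assert wrap_angle(-180.0) == 180.0
    assert wrap_angle(540.0) == 180.0
    assert np.allclose(wrap_angle([10.0, -350.0]), [10.0, 10.0])
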