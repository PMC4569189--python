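"""Boundary-point extraction, contact indices and anatomical labels."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from gpilead.coords import build_frame
from gpilead.gpi import (
    ContactOutsideStructureError,
    DegenerateBoundaryError,
    GpiBoundaryFix,
    boundary_points,
    classify_contact,
    indices,
    locate_contact,
)
from gpilead.synth import (
    SimulationConfig,
    _sample_shape,
    analytic_boundary_points,
    gen_structure_masks,
)
from conftest import make_box_mask, random_rigid_motion


class TestBoundaryPointsBox:
    def test_box_geometry(self, frame, box_mask):
        fix = boundary_points(box_mask, frame, [15.0, 2.0, -2.0])
        assert fix.A[1] == pytest.approx(5.0, abs=0.1)
        assert fix.P[1] == pytest.approx(-5.0, abs=0.1)
        np.testing.assert_allclose(fix.M, [10.0, 2.0, -2.0], atol=0.1)
        np.testing.assert_allclose(fix.L, [20.0, 2.0, -2.0], atol=0.1)
        np.testing.assert_allclose(fix.V, [15.0, 2.0, -4.0], atol=0.1)
        np.testing.assert_allclose(fix.D, [15.0, 2.0, 0.0], atol=0.1)

    def test_contact_outside_axial_slab(self, frame, box_mask):
        with pytest.raises(ContactOutsideStructureError):
            boundary_points(box_mask, frame, [15.0, 2.0, 15.0])

    def test_line_missing_structure(self, frame, box_mask):
        # inside the axial slab but laterally far off: the VD line misses
        with pytest.raises(ContactOutsideStructureError):
            boundary_points(box_mask, frame, [45.0, 2.0, -2.0])


class TestBoundaryPointsEllipsoid:
    def test_matches_analytic_ellipsoid_oracle(self, frame):
        """Mask-derived boundary points sit within one voxel diagonal of
        the closed-form ellipsoid-line intersections."""
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(20)
        for _ in range(15):
            shape = _sample_shape(cfg, frame, "right", rng)
            masks = gen_structure_masks(cfg, shape, "right")
            vdiag = masks.gpi.voxel_diagonal
            for _ in range(4):
                c = shape.center + (rng.uniform(-0.7, 0.7, 3) * shape.semi_axes) @ frame.axes
                if shape.quadratic(c)[0] > 0.6:
                    continue
                fix = boundary_points(masks.gpi, frame, c)
                afix = analytic_boundary_points(shape, frame, c)
                for name in "APMLVD":
                    d = np.linalg.norm(getattr(fix, name) - getattr(afix, name))
                    assert d < vdiag, f"{name} off by {d:.2f} mm"

    def test_convex_mask_single_run(self, frame):
        """On a convex mask each required line has one entry and one exit:
        boundary points are the same whichever side of the structure the
        interior contact sits on."""
        cfg = SimulationConfig(seed=1)
        rng = np.random.default_rng(21)
        shape = _sample_shape(cfg, frame, "right", rng)
        masks = gen_structure_masks(cfg, shape, "right")
        c1 = shape.center + np.array([0.0, 2.0, 0.0])
        c2 = shape.center + np.array([0.0, -2.0, 0.0])
        f1 = boundary_points(masks.gpi, frame, c1)
        f2 = boundary_points(masks.gpi, frame, c2)
        # A/P come from the same axial slice scan in both cases
        np.testing.assert_allclose(f1.A, f2.A, atol=1e-9)
        np.testing.assert_allclose(f1.P, f2.P, atol=1e-9)


class TestIndices:
    def test_projection_fixture(self):
        """A 10 mm AP segment with the contact 3.8 mm above P gives 0.62."""
        fix = GpiBoundaryFix(
            A=np.array([0.0, 10.0, 0.0]),
            P=np.array([0.0, 0.0, 0.0]),
            M=np.array([-5.0, 5.0, 0.0]),
            L=np.array([5.0, 5.0, 0.0]),
            V=np.array([0.0, 5.0, -4.0]),
            D=np.array([0.0, 5.0, 4.0]),
            contact=np.array([3.0, 3.8, 0.0]),
        )
        out = indices(fix)
        assert out.ap_index == pytest.approx(0.62)
        np.testing.assert_allclose(out.S_ap, [0.0, 3.8, 0.0], atol=1e-12)

    def test_midpoint_contact_gives_half_everywhere(self, frame, box_mask):
        out = locate_contact(box_mask, frame, [15.0, 0.0, -2.0])
        assert out.ap_index == pytest.approx(0.5, abs=0.01)
        assert out.ml_index == pytest.approx(0.5, abs=0.01)
        assert out.vd_index == pytest.approx(0.5, abs=0.01)

    def test_projection_agrees_with_minimizer_oracle(self):
        """The projection parameter equals the argmin of the distance
        from the contact to the segment (independent 1D optimizer)."""
        rng = np.random.default_rng(22)
        for _ in range(50):
            a, b, c = rng.normal(scale=10, size=(3, 3))
            fix = GpiBoundaryFix(
                A=a, P=b, M=a + 1, L=b + 1, V=a - 1, D=b - 1, contact=c
            )
            out = indices(fix)
            res = minimize_scalar(
                lambda t: np.linalg.norm(c - (a + t * (b - a))),
                bounds=(-10.0, 10.0), method="bounded",
                options={"xatol": 1e-12},
            )
            assert out.ap_index == pytest.approx(res.x, abs=1e-6)

    def test_posterior_motion_is_monotone(self, frame, box_mask):
        """Moving the contact posteriorly never decreases the AP-index."""
        ap_vals = np.linspace(4.0, -4.0, 9)
        idx = [
            locate_contact(box_mask, frame, [15.0, ap, -2.0]).ap_index
            for ap in ap_vals
        ]
        assert all(b >= a - 1e-12 for a, b in zip(idx, idx[1:]))

    def test_degenerate_segment_rejected(self):
        z = np.zeros(3)
        fix = GpiBoundaryFix(A=z, P=z, M=z, L=z, V=z, D=z, contact=z)
        with pytest.raises(DegenerateBoundaryError):
            indices(fix)

    def test_rigid_motion_invariance(self, frame):
        """Indices computed after rotating mask, frame and contact
        jointly match the unrotated ones."""
        cfg = SimulationConfig(seed=2)
        rng = np.random.default_rng(23)
        shape = _sample_shape(cfg, frame, "right", rng)
        masks = gen_structure_masks(cfg, shape, "right")
        contact = shape.center + np.array([0.5, -2.0, -1.5])
        ref = locate_contact(masks.gpi, frame, contact)
        for _ in range(3):
            R, t = random_rigid_motion(rng)
            moved_affine = np.eye(4)
            moved_affine[:3, :3] = R @ masks.gpi.affine[:3, :3]
            moved_affine[:3, 3] = R @ masks.gpi.affine[:3, 3] + t
            moved_mask = type(masks.gpi)(masks.gpi.data, moved_affine, label="GPi")
            moved_frame = build_frame(
                R @ frame.ac + t, R @ frame.pc + t, R @ frame.midsagittal_normal
            )
            out = locate_contact(moved_mask, moved_frame, R @ contact + t)
            assert out.ap_index == pytest.approx(ref.ap_index, abs=0.02)
            assert out.ml_index == pytest.approx(ref.ml_index, abs=0.02)
            assert out.vd_index == pytest.approx(ref.vd_index, abs=0.02)


class TestClassifyContact:
    def test_centroid_is_inside(self, box_mask):
        loc = classify_contact([15.0, 0.0, -2.0], box_mask, delta=0.65)
        assert loc.label == "GPi"

    def test_near_gpe_interface(self, box_mask):
        gpe = make_box_mask((20, 26), (-5, 5), (-4, 0), label="GPe")
        loc = classify_contact([19.7, 0.0, -2.0], box_mask, gpe=gpe, delta=0.65)
        assert loc.label == "GPi/GPe"
        assert loc.distance_to_gpe == pytest.approx(0.3, abs=1e-6)

    def test_near_ic_interface(self, box_mask):
        ic = make_box_mask((7, 10), (-5, 5), (-4, 0), label="IC")
        loc = classify_contact([10.3, 0.0, -2.0], box_mask, ic=ic, delta=0.65)
        assert loc.label == "IC/GPi"

    def test_far_point_is_outside(self, box_mask):
        loc = classify_contact([40.0, 0.0, -2.0], box_mask, delta=0.65)
        assert loc.label == "outside"

    def test_missing_neighbor_masks_restrict_labels(self, box_mask):
        loc = classify_contact([15.0, 0.0, -2.0], box_mask, delta=0.65)
        assert "GPi/GPe" not in loc.reachable_labels
        assert "IC/GPi" not in loc.reachable_labels

    def test_nonpositive_delta_rejected(self, box_mask):
        with pytest.raises(ValueError):
            classify_contact([15.0, 0.0, -2.0], box_mask, delta=0.0)
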