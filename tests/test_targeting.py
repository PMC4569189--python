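"""Atlas rules, target differences and lead targeting errors."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from gpilead.coords import StereoCoordinates, build_frame, stereo_to_world
from gpilead.lead import LeadObservation, MODEL_3389, lead_direction
from gpilead.targeting import (
    InvalidMeasurementsError,
    NoIntersectionError,
    TargetPair,
    atlas_target,
    closest_lead_distance,
    delta_targets,
    targeting_error,
)
from conftest import random_rigid_motion


class TestAtlasTarget:
    def test_short_acpc_gives_ap_two(self):
        assert atlas_target(6.0, 24.0).ap == pytest.approx(2.0)

    def test_long_acpc_gives_ap_three(self):
        assert atlas_target(6.0, 26.0).ap == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "width,lat", [(1.0, 20.0), (2.0, 20.0), (6.0, 21.0), (10.0, 22.0), (12.0, 22.0)]
    )
    def test_ventricle_width_interpolation(self, width, lat):
        assert atlas_target(width, 25.0).lat == pytest.approx(lat)

    def test_vertical_default(self):
        assert atlas_target(6.0, 25.0).vert == pytest.approx(-1.5)

    def test_invalid_measurements(self):
        with pytest.raises(InvalidMeasurementsError):
            atlas_target(0.0, 25.0)
        with pytest.raises(InvalidMeasurementsError):
            atlas_target(5.0, -1.0)


class TestDeltaTargets:
    def _pair(self, a, d):
        return TargetPair(
            atlas=StereoCoordinates(*a, hemisphere="right"),
            direct=StereoCoordinates(*d, hemisphere="right"),
        )

    def test_identical_targets_give_zero(self):
        dt = delta_targets(self._pair((20, 2, -1.5), (20, 2, -1.5)))
        assert (dt.d_lat, dt.d_ap, dt.d_vert, dt.d_euclid) == (0, 0, 0, 0)

    def test_single_axis_offset(self):
        dt = delta_targets(self._pair((21, 2, -1.5), (20, 2, -1.5)))
        assert dt.d_euclid == pytest.approx(1.0)

    def test_euclidean_of_mean_cohort_deltas(self):
        """The per-axis mean differences between planning methods (1.13,
        0.61, 1.31 mm) combine to a 1.84 mm norm — smaller than the
        reported mean Euclidean difference, which averages per-lead
        norms rather than taking the norm of the means."""
        dt = delta_targets(self._pair((21.13, 2.61, -1.5), (20.0, 2.0, -2.81)))
        assert (dt.d_lat, dt.d_ap, dt.d_vert) == pytest.approx((1.13, 0.61, 1.31))
        assert dt.d_euclid == pytest.approx(
            np.sqrt(1.13**2 + 0.61**2 + 1.31**2), abs=1e-12
        )
        assert dt.d_euclid == pytest.approx(1.834, abs=5e-4)

    def test_mixed_hemisphere_pair_rejected(self):
        with pytest.raises(ValueError):
            TargetPair(
                atlas=StereoCoordinates(20, 2, -1.5, hemisphere="left"),
                direct=StereoCoordinates(20, 2, -1.5, hemisphere="right"),
            )


class TestTargetingError:
    def test_lead_through_target(self, frame):
        target = StereoCoordinates(20.0, 2.0, -2.0, hemisphere="right")
        tw = stereo_to_world(frame, target)
        u = np.array([0.2, 0.3, 1.0])
        u /= np.linalg.norm(u)
        obs = LeadObservation(tip=tw - 4 * u, shaft=tw + 21 * u)
        err = targeting_error(target, obs, frame)
        assert err.d_euclid == pytest.approx(0.0, abs=1e-9)

    def test_unit_offsets_give_sqrt_two(self, frame):
        target = StereoCoordinates(20.0, 2.0, -2.0, hemisphere="right")
        tw = stereo_to_world(frame, target) + np.array([1.0, 1.0, 0.0])
        obs = LeadObservation(tip=tw - np.array([0, 0, 5]), shaft=tw + np.array([0, 0, 20]))
        err = targeting_error(target, obs, frame)
        assert err.d_lat == pytest.approx(1.0)
        assert err.d_ap == pytest.approx(1.0)
        assert err.d_euclid == pytest.approx(np.sqrt(2.0))

    def test_three_four_five_construction(self, frame):
        target = StereoCoordinates(20.0, 2.0, -2.0, hemisphere="right")
        tw = stereo_to_world(frame, target) + np.array([0.8, 0.6, 0.0])
        obs = LeadObservation(tip=tw - np.array([0, 0, 5]), shaft=tw + np.array([0, 0, 20]))
        err = targeting_error(target, obs, frame)
        assert err.d_euclid == pytest.approx(1.0, abs=1e-12)

    def test_horizontal_lead_rejected(self, frame):
        target = StereoCoordinates(20.0, 2.0, -2.0, hemisphere="right")
        obs = LeadObservation(tip=[0, 0, 5], shaft=[10, 0, 5])
        with pytest.raises(NoIntersectionError):
            targeting_error(target, obs, frame)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(30)
        ac, pc, n = np.array([0, 12.5, 0]), np.array([0, -12.5, 0]), np.array([1.0, 0, 0])
        frame = build_frame(ac, pc, n)
        target = StereoCoordinates(19.0, 2.5, -2.5, hemisphere="left")
        tip = np.array([-19.5, 1.0, -6.0])
        shaft = np.array([-15.0, 11.0, 18.0])
        ref = targeting_error(target, LeadObservation(tip=tip, shaft=shaft), frame)
        for _ in range(10):
            R, t = random_rigid_motion(rng)
            moved_frame = build_frame(R @ ac + t, R @ pc + t, R @ n)
            moved = LeadObservation(tip=R @ tip + t, shaft=R @ shaft + t)
            err = targeting_error(target, moved, moved_frame)
            assert err.d_euclid == pytest.approx(ref.d_euclid, abs=1e-9)
            assert err.d_ap == pytest.approx(ref.d_ap, abs=1e-9)
            assert err.d_lat == pytest.approx(ref.d_lat, abs=1e-9)


class TestClosestLeadDistance:
    def test_target_on_segment_gives_zero(self, frame):
        tip = np.array([20.0, 2.0, -8.0])
        obs = LeadObservation(tip=tip, shaft=tip + np.array([0, 0, 25.0]))
        target = StereoCoordinates(20.0, 2.0, -4.0, hemisphere="right")
        d = closest_lead_distance(target, obs, frame)
        assert d.d_euclid == pytest.approx(0.0, abs=1e-12)

    def test_lateral_offset_only(self, frame):
        tip = np.array([20.0, 2.0, -8.0])
        obs = LeadObservation(tip=tip, shaft=tip + np.array([0, 0, 25.0]))
        target = StereoCoordinates(21.0, 2.0, -4.0, hemisphere="right")
        d = closest_lead_distance(target, obs, frame)
        assert d.d_lat == pytest.approx(1.0)
        assert d.d_ap == pytest.approx(0.0, abs=1e-12)
        assert d.d_vert == pytest.approx(0.0, abs=1e-12)
        assert d.d_euclid == pytest.approx(1.0)

    def test_agrees_with_dense_sampling_oracle(self, frame):
        """Closest point on the contact-bearing segment, found by an
        independent bounded 1D minimizer over the segment parameter."""
        rng = np.random.default_rng(31)
        k_lo, k_hi = MODEL_3389.span
        for _ in range(100):
            tip = rng.normal(scale=15, size=3)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            obs = LeadObservation(tip=tip, shaft=tip + 25 * u)
            t_stereo = rng.uniform([0, -20, -20], [30, 20, 20])
            target = StereoCoordinates(
                t_stereo[0], t_stereo[1], t_stereo[2],
                hemisphere=rng.choice(["left", "right"]),
            )
            tw = stereo_to_world(frame, target)
            res = minimize_scalar(
                lambda k: np.linalg.norm(tip + k * u - tw),
                bounds=(k_lo, k_hi), method="bounded",
                options={"xatol": 1e-10},
            )
            d = closest_lead_distance(target, obs, frame)
            assert d.d_euclid == pytest.approx(res.fun, abs=1e-6)

    def test_euclid_dominates_axis_components(self, frame):
        rng = np.random.default_rng(32)
        for _ in range(50):
            tip = rng.normal(scale=15, size=3)
            obs = LeadObservation(tip=tip, shaft=tip + rng.normal(size=3) * 20)
            target = StereoCoordinates(
                rng.uniform(0, 30), rng.uniform(-20, 20), rng.uniform(-20, 20),
                hemisphere="right",
            )
            try:
                d = closest_lead_distance(target, obs, frame)
            except Exception:
                continue
            assert d.d_euclid <= d.d_lat + d.d_ap + d.d_vert + 1e-12
            assert d.d_euclid >= max(d.d_lat, d.d_ap, d.d_vert) - 1e-12
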