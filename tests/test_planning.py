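import math

import numpy as np
import pytest

from kneeplan.decoding import FeatureSet, NotDetected
from kneeplan.geometry import (
    Calibration,
    CalibrationSource,
    Keypoint,
    PolygonRegion,
    Polyline,
    SimilarityTransform,
    apply_similarity,
)
from kneeplan.planning import (
    Application,
    PlanBlueprint,
    execute_plan,
    plan_acl_femur,
    plan_acl_tibia,
    plan_mpfl,
    plan_pcl,
)

CAL = Calibration(mm_per_px=0.5, source=CalibrationSource.manual)


def _fs(*features):
    fs = FeatureSet()
    for f in features:
        fs.add(f)
    return fs


def _transform_fs(fs, t):
    out = FeatureSet()
    for pool in (fs.keypoints, fs.lines, fs.regions):
        for f in pool.values():
            out.add(apply_similarity(f, t))
    return out


class TestMpfl:
    def _features(self):
        cortex = Polyline(points=np.array([[100.0, 40.0], [100.0, 90.0], [100.0, 140.0]]), label="L1")
        return _fs(Keypoint(140.0, 80.0, label="K3"), Keypoint(140.0, 160.0, label="K7"), cortex)

    def test_vertical_cortex_oracle(self):
        # feet of (140,80) and (140,160) on x=100 are (100,80) and (100,160)
        plan = plan_mpfl(self._features())
        assert plan.ok
        target = plan.targets["schoettle"]
        assert target.x == pytest.approx(100.0, abs=1e-9)
        assert target.y == pytest.approx(120.0, abs=1e-9)

    def test_random_configurations_match_analytic_oracle(self, rng):
        for _ in range(100):
            origin = rng.uniform(50, 200, 2)
            theta = rng.uniform(0, math.pi)
            d = np.array([math.cos(theta), math.sin(theta)])
            ts = np.sort(rng.uniform(-60, 60, 5))
            cortex = Polyline(points=origin + np.outer(ts, d), label="L1")
            normal = np.array([-d[1], d[0]])
            kp_a = origin + rng.uniform(-50, 50) * d + rng.uniform(10, 60) * normal
            kp_b = origin + rng.uniform(-50, 50) * d + rng.uniform(10, 60) * normal
            fs = _fs(
                Keypoint(*kp_a, label="K3"), Keypoint(*kp_b, label="K7"), cortex
            )
            plan = plan_mpfl(fs)
            assert plan.ok
            # independent oracle: project both keypoints with the dot-product formula
            feet = [origin + float((p - origin) @ d) * d for p in (kp_a, kp_b)]
            expected = 0.5 * (feet[0] + feet[1])
            assert plan.targets["schoettle"].x == pytest.approx(expected[0], abs=1e-6)
            assert plan.targets["schoettle"].y == pytest.approx(expected[1], abs=1e-6)

    def test_similarity_equivariance(self, rng):
        fs = self._features()
        base = plan_mpfl(fs).targets["schoettle"]
        t = SimilarityTransform(angle_deg=33.0, scale=1.7, tx=12.0, ty=-8.0)
        moved = plan_mpfl(_transform_fs(fs, t)).targets["schoettle"]
        expected = t.apply(base.xy)[0]
        assert moved.x == pytest.approx(expected[0], abs=1e-6)
        assert moved.y == pytest.approx(expected[1], abs=1e-6)

    def test_missing_cortex_cancels(self):
        fs = _fs(Keypoint(140.0, 80.0, label="K3"), Keypoint(140.0, 160.0, label="K7"))
        plan = plan_mpfl(fs)
        assert plan.status == "cancelled"
        assert "cortex" in plan.reason

    def test_coincident_keypoints_cancel(self):
        cortex = Polyline(points=np.array([[100.0, 40.0], [100.0, 140.0]]), label="L1")
        fs = _fs(Keypoint(140.0, 80.0, label="K3"), Keypoint(140.0, 80.0, label="K7"), cortex)
        assert plan_mpfl(fs).status == "cancelled"

    def test_tolerance_circle_when_calibrated(self):
        plan = plan_mpfl(self._features(), cal=CAL)
        assert plan.tolerance_radius_px == pytest.approx(2.5 / 0.5)


class TestAclFemur:
    def _features(self, rot_deg=0.0):
        square = PolygonRegion(
            shell=np.array([[100.0, 100.0], [200.0, 100.0], [200.0, 200.0], [100.0, 200.0]]),
            label="S1",
        )
        fs = _fs(Keypoint(100.0, 100.0, label="K1"), Keypoint(200.0, 100.0, label="K2"), square)
        if rot_deg:
            fs = _transform_fs(fs, SimilarityTransform(angle_deg=rot_deg))
        return fs

    def test_unit_square_fractions(self):
        bp = PlanBlueprint(
            application=Application.ACL_FEMUR,
            constants={"am_frac_u": 0.25, "am_frac_v": 0.25, "pl_frac_u": 0.5, "pl_frac_v": 0.75},
        )
        plan = plan_acl_femur(self._features(), bp)
        assert plan.ok
        am = plan.targets["am"]
        # frame: u along K1->K2 (+x), v towards the contour body (+y), extents 100x100
        assert am.x == pytest.approx(125.0, abs=1e-9)
        assert am.y == pytest.approx(125.0, abs=1e-9)
        pl = plan.targets["pl"]
        assert pl.x == pytest.approx(150.0, abs=1e-9)
        assert pl.y == pytest.approx(175.0, abs=1e-9)

    def test_rotation_equivariance(self):
        base = plan_acl_femur(self._features())
        rotated = plan_acl_femur(self._features(rot_deg=37.0))
        t = SimilarityTransform(angle_deg=37.0)
        for name in ("am", "pl"):
            expected = t.apply(base.targets[name].xy)[0]
            assert rotated.targets[name].x == pytest.approx(expected[0], abs=1e-6)
            assert rotated.targets[name].y == pytest.approx(expected[1], abs=1e-6)

    def test_out_of_range_fraction_rejected_at_load(self):
        with pytest.raises(ValueError):
            PlanBlueprint(application=Application.ACL_FEMUR, constants={"am_frac_u": 1.2})

    def test_missing_contour_cancels(self):
        fs = _fs(Keypoint(100.0, 100.0, label="K1"), Keypoint(200.0, 100.0, label="K2"))
        assert plan_acl_femur(fs).status == "cancelled"


class TestAclTibia:
    def test_linear_interpolation(self):
        fs = _fs(Keypoint(0.0, 0.0, label="K4"), Keypoint(100.0, 0.0, label="K5"))
        bp = PlanBlueprint(application=Application.ACL_TIBIA, constants={"am_frac": 0.3, "pl_frac": 0.52})
        plan = plan_acl_tibia(fs, bp)
        assert plan.targets["am"].x == pytest.approx(30.0)
        assert plan.targets["pl"].x == pytest.approx(52.0)

    def test_fraction_boundaries(self):
        fs = _fs(Keypoint(10.0, 20.0, label="K4"), Keypoint(110.0, 90.0, label="K5"))
        bp0 = PlanBlueprint(application=Application.ACL_TIBIA, constants={"am_frac": 0.0, "pl_frac": 1.0})
        plan = plan_acl_tibia(fs, bp0)
        assert (plan.targets["am"].x, plan.targets["am"].y) == (10.0, 20.0)
        assert (plan.targets["pl"].x, plan.targets["pl"].y) == (110.0, 90.0)

    def test_scale_equivariance(self):
        fs = _fs(Keypoint(10.0, 20.0, label="K4"), Keypoint(110.0, 80.0, label="K5"))
        base = plan_acl_tibia(fs)
        scaled = plan_acl_tibia(_transform_fs(fs, SimilarityTransform(scale=2.0)))
        for name in ("am", "pl"):
            assert scaled.targets[name].x == pytest.approx(2.0 * base.targets[name].x, abs=1e-9)
            assert scaled.targets[name].y == pytest.approx(2.0 * base.targets[name].y, abs=1e-9)

    def test_coincident_endpoints_cancel(self):
        fs = _fs(Keypoint(10.0, 20.0, label="K4"), Keypoint(10.0, 20.0, label="K5"))
        assert plan_acl_tibia(fs).status == "cancelled"


class TestPcl:
    def _features(self):
        line = Polyline(points=np.array([[200.0, 300.0], [300.0, 300.0]]), label="L3")
        return _fs(Keypoint(200.0, 300.0, label="K6"), line)

    def test_metric_offset_arithmetic(self):
        # 10 mm at 0.5 mm/px = 20 px along the +x reference line
        bp = PlanBlueprint(application=Application.PCL, constants={"offset_mm": 10.0, "wire_angle_deg": 0.0})
        plan = plan_pcl(self._features(), bp, cal=CAL)
        assert plan.ok
        assert plan.targets["insertion"].x == pytest.approx(220.0, abs=1e-9)
        assert plan.targets["insertion"].y == pytest.approx(300.0, abs=1e-9)

    def test_zero_wire_angle_parallel(self):
        bp = PlanBlueprint(application=Application.PCL, constants={"wire_angle_deg": 0.0})
        plan = plan_pcl(self._features(), bp, cal=CAL)
        wire = plan.wires["guidewire"].points
        d = wire[-1] - wire[0]
        assert abs(d[1] / np.linalg.norm(d)) < 1e-9  # parallel to the +x reference
        assert plan.wire_angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_uncalibrated_refused(self):
        plan = plan_pcl(self._features(), cal=Calibration())
        assert plan.status == "cancelled"
        assert plan.reason == "no-scale"

    def test_missing_reference_cancels(self):
        fs = _fs(Keypoint(200.0, 300.0, label="K6"))
        assert plan_pcl(fs, cal=CAL).status == "cancelled"


class TestExecutePlan:
    def _fs(self):
        cortex = Polyline(points=np.array([[100.0, 40.0], [100.0, 140.0]]), label="L1")
        return _fs(Keypoint(140.0, 80.0, label="K3"), Keypoint(140.0, 160.0, label="K7"), cortex)

    def test_empty_edits_identical(self):
        bp = PlanBlueprint.default(Application.MPFL)
        a = plan_mpfl(self._fs(), bp)
        b = execute_plan(self._fs(), bp, edits={})
        assert a.targets["schoettle"].xy == pytest.approx(b.targets["schoettle"].xy)

    def test_edit_moves_target_deterministically(self):
        bp = PlanBlueprint.default(Application.MPFL)
        edit = {"kp_a": Keypoint(140.0, 100.0, label="ignored")}
        a = execute_plan(self._fs(), bp, edits=edit)
        b = execute_plan(self._fs(), bp, edits=edit)
        assert a.targets["schoettle"].y == pytest.approx(130.0)
        assert a.targets["schoettle"].xy == pytest.approx(b.targets["schoettle"].xy)
        assert a.intermediates["foot_a"].y == pytest.approx(100.0)

    def test_unknown_role_rejected(self):
        bp = PlanBlueprint.default(Application.MPFL)
        with pytest.raises(KeyError):
            execute_plan(self._fs(), bp, edits={"nonexistent_role": Keypoint(0.0, 0.0)})

    def test_independent_applications_unaffected_by_edit(self):
        fs = self._fs()
        fs.add(Keypoint(10.0, 20.0, label="K4"))
        fs.add(Keypoint(110.0, 20.0, label="K5"))
        bp_tibia = PlanBlueprint.default(Application.ACL_TIBIA)
        before = execute_plan(fs, bp_tibia)
        # editing an MPFL input feature leaves the tibial plan bit-identical
        execute_plan(fs, PlanBlueprint.default(Application.MPFL), edits={"kp_a": Keypoint(1.0, 2.0)})
        after = execute_plan(fs, bp_tibia)
        assert before.targets["am"].xy == pytest.approx(after.targets["am"].xy, abs=0)

    def test_never_crashes_on_empty_features(self):
        for app in Application:
            plan = execute_plan(FeatureSet(), PlanBlueprint.default(app), cal=CAL)
            assert plan.status == "cancelled"
            assert plan.reason
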