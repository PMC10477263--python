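"""Geometric Cobb-angle extraction: inclinations, extrema, curves, labels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cobbkit import cobb
from cobbkit.core import Curve, LandmarkSet, N_VERTEBRAE

from oracles import brute_force_curves


def rect(cx, cy, w, h, angle_deg=0.0):
    """(UL, UR, LL, LR) corners of a rotated rectangle."""
    r = math.radians(angle_deg)
    rot = np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])
    local = np.array([[-w / 2, -h / 2], [w / 2, -h / 2], [-w / 2, h / 2], [w / 2, h / 2]])
    return local @ rot.T + [cx, cy]


class TestInclination:
    def test_axis_aligned_rectangle_is_level(self):
        assert cobb.vertebra_inclination(rect(0, 0, 10, 4)) == pytest.approx(0.0)

    @pytest.mark.parametrize("angle", [10.0, -25.0, 45.0, 89.0])
    def test_rigid_rotation_recovered(self, angle):
        assert cobb.vertebra_inclination(rect(5, 5, 10, 4, angle)) == pytest.approx(angle)

    def test_trapezoid_midline_matches_direct_atan2(self):
        # vertical sides, top edge at 8 deg, bottom edge at 12 deg
        w = 10.0
        ul, ur = np.array([0.0, 0.0]), np.array([w, w * math.tan(math.radians(8))])
        ll = np.array([0.0, 6.0])
        lr = np.array([w, 6.0 + w * math.tan(math.radians(12))])
        got = cobb.vertebra_inclination(np.array([ul, ur, ll, lr]))
        mid_l, mid_r = (ul + ll) / 2, (ur + lr) / 2
        expect = math.degrees(math.atan2(*(mid_r - mid_l)[::-1]))
        assert got == pytest.approx(expect, abs=1e-12)

    def test_edge_mean_mode_coincides_on_parallelograms(self, rng):
        for _ in range(20):
            base = rect(0, 0, 12, 5, rng.uniform(-30, 30))
            shear = rng.uniform(-3, 3, size=2)
            base[1] += shear  # UR
            base[3] += shear  # LR -> still a parallelogram
            a = cobb.vertebra_inclination(base, mode="midline")
            b = cobb.vertebra_inclination(base, mode="edge-mean")
            assert a == pytest.approx(b, abs=1e-9)

    def test_zero_area_rejected(self):
        degenerate = np.array([[0, 0], [1, 0], [0, 0], [1, 0]], dtype=float)
        with pytest.raises(ValueError, match="zero area"):
            cobb.vertebra_inclination(degenerate)


class TestFindExtrema:
    def test_constant_profile_gives_only_endpoints(self):
        assert cobb.find_extrema(np.zeros(17)) == [0, 16]

    def test_monotone_profile_gives_only_endpoints(self):
        assert cobb.find_extrema(np.linspace(-20, 20, 17)) == [0, 16]

    def test_interior_max_and_min_survive_filter(self):
        v = np.zeros(17)
        v[6], v[11] = 12.0, -10.0
        assert cobb.find_extrema(v) == [0, 6, 11, 16]

    def test_small_wiggle_pair_removed(self):
        v = np.zeros(17)
        v[5], v[7] = 2.0, -2.0  # |diff| = 4 < 5 -> both removed
        assert cobb.find_extrema(v) == [0, 16]

    def test_single_member_removal_variant(self):
        v = np.zeros(17)
        v[5], v[7] = 2.0, -10.0
        # pair removal: |2-(-10)| = 12 >= 5 -> both stay
        assert cobb.find_extrema(v, pair_removal=True) == [0, 5, 7, 16]
        # single-member variant drops only the less extreme on close pairs
        v2 = np.zeros(17)
        v2[5], v2[7] = 4.0, 1.0
        assert 7 not in cobb.find_extrema(v2, pair_removal=False)


class TestExtractCurves:
    def test_straight_profile_has_no_curves(self):
        assert len(cobb.extract_curves(np.zeros(17))) == 0

    def test_s_shape_hand_case(self):
        # T1 0 -> peak +20 at T7 (idx 6) -> trough -15 at L2 (idx 13) -> 0 at L5
        v = np.concatenate(
            [np.linspace(0, 20, 7), np.linspace(20, -15, 8)[1:], np.linspace(-15, 0, 4)[1:]]
        )
        assert len(v) == 17 and v[6] == 20 and v[13] == -15
        cs = cobb.extract_curves(v)
        got = {(c.upper_end, c.lower_end): round(c.cobb_angle, 6) for c in cs}
        assert got == {(0, 6): 20.0, (6, 13): 35.0, (13, 16): 15.0}
        assert cs.major.cobb_angle == pytest.approx(35.0)
        assert cs.by_rank("minor1").cobb_angle == pytest.approx(20.0)
        assert cs.by_rank("minor2").region == "lumbar"

    def test_matches_brute_force_on_random_profiles(self, rng):
        for _ in range(300):
            v = rng.uniform(-25, 25, size=17)
            expected = brute_force_curves(v)
            got = cobb.extract_curves(v)
            raw = sorted(
                (c.upper_end, c.lower_end, round(c.cobb_angle, 9))
                for c in _unfiltered_curves(v)
            )
            assert raw == sorted((a, b, round(ang, 9)) for a, b, ang in expected)
            # ranked curves are a subset of the enumerated ones
            for c in got:
                assert (c.upper_end, c.lower_end, round(c.cobb_angle, 9)) in raw


def _unfiltered_curves(v):
    """All adjacent-extrema curves >= 5 deg, before region/rank capping."""
    ends = cobb.find_extrema(v)
    out = []
    for a, b in zip(ends, ends[1:]):
        ang = abs(v[a] - v[b])
        if ang >= cobb.MIN_CURVE_DIFF_DEG:
            out.append(Curve(a, b, float(ang)))
    return out


class TestLabelCurves:
    def test_two_thoracic_one_lumbar_ordering(self):
        curves = [
            Curve(0, 5, 40.0, region="thoracic"),
            Curve(5, 10, 25.0, region="thoracic"),
            Curve(11, 16, 18.0, region="lumbar"),
        ]
        out = cobb.label_curves(curves)
        assert [(c.rank, c.cobb_angle) for c in out] == [
            ("major", 40.0), ("minor1", 25.0), ("minor2", 18.0)
        ]

    def test_third_thoracic_dropped(self):
        curves = [
            Curve(0, 4, 30.0, region="thoracic"),
            Curve(4, 8, 20.0, region="thoracic"),
            Curve(8, 11, 10.0, region="thoracic"),
            Curve(11, 16, 15.0, region="lumbar"),
        ]
        out = cobb.label_curves(curves)
        kept = {c.cobb_angle for c in out}
        assert kept == {30.0, 20.0, 15.0}
        # exhaustive check of the keep-rule: top-2 thoracic + top-1 lumbar
        thoracic = sorted([30.0, 20.0, 10.0], reverse=True)[:2]
        lumbar = [15.0]
        assert kept == set(thoracic + lumbar)

    def test_single_curve_is_major(self):
        out = cobb.label_curves([Curve(2, 9, 22.0, region="thoracic")])
        assert [c.rank for c in out] == ["major"]


class TestMeasureInvariances:
    def _rotate(self, landmarks, theta_deg, center):
        r = math.radians(theta_deg)
        rot = np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])
        pts = (landmarks.points.reshape(-1, 2) - center) @ rot.T + center
        return LandmarkSet(pts.reshape(N_VERTEBRAE, 4, 2))

    @pytest.mark.parametrize("theta", [-15.0, -5.0, 5.0, 15.0])
    def test_global_rotation_shifts_inclinations_not_angles(self, curved_case, theta):
        base = cobb.measure(curved_case.landmarks)
        rotated = cobb.measure(self._rotate(curved_case.landmarks, theta, np.array([192, 384])))
        np.testing.assert_allclose(
            rotated.inclinations, base.inclinations + theta, atol=1e-6
        )
        for a, b in zip(base.curves, rotated.curves):
            assert (a.upper_end, a.lower_end) == (b.upper_end, b.lower_end)
            assert a.cobb_angle == pytest.approx(b.cobb_angle, abs=1e-6)

    def test_translation_and_scale_invariance(self, curved_case):
        base = cobb.measure(curved_case.landmarks)
        moved = cobb.measure(LandmarkSet(curved_case.landmarks.points * 2.0 + [37.0, -11.0]))
        for a, b in zip(base.curves, moved.curves):
            assert (a.upper_end, a.lower_end, a.rank) == (b.upper_end, b.lower_end, b.rank)
            assert a.cobb_angle == pytest.approx(b.cobb_angle, abs=1e-9)

    def test_incomplete_landmarks_rejected(self, curved_case):
        lm = curved_case.landmarks.copy()
        lm.present[3, 2] = False
        with pytest.raises(ValueError, match="incomplete"):
            cobb.measure(lm)


@given(st.lists(st.floats(-40, 40), min_size=17, max_size=17))
@settings(max_examples=200, deadline=None)
def test_extrema_filter_is_stable(values):
    """Re-filtering the surviving adjacent interior extrema changes nothing."""
    v = np.asarray(values)
    ends = cobb.find_extrema(v)
    assert ends[0] == 0 and ends[-1] == 16 and ends == sorted(set(ends))
    interior = [i for i in ends if 0 < i < 16]
    # all adjacent interior extremum pairs differ by at least the threshold
    for a, b in zip(interior, interior[1:]):
        assert abs(v[a] - v[b]) >= cobb.MIN_CURVE_DIFF_DEG
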