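"""Landmark geometry: rigid motions, levers and angles."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import jawlever as jl
from jawlever.geometry import GeometryError, muscle_line_length


def _cloud(coords, **extra):
    pts = {str(i + 1): c for i, c in enumerate(coords)}
    pts.update(extra)
    return jl.LandmarkSet(points=pts)


def _pairwise_distances(lm):
    keys = sorted(lm.points)
    pts = np.array([lm.points[k] for k in keys])
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff**2).sum(-1))


finite_coord = st.floats(-100, 100, allow_nan=False)
point = st.tuples(finite_coord, finite_coord)


class TestRotateToHorizontal:
    def test_already_horizontal_is_identity(self):
        lm = _cloud([(0, 0), (10, 0), (3, 5)])
        out = jl.rotate_to_horizontal(lm, ("1", "2"))
        for k in lm.points:
            np.testing.assert_allclose(out.points[k], lm.points[k], atol=1e-12)

    def test_quarter_turn(self):
        lm = _cloud([(0, 0), (0, 1)])
        out = jl.rotate_to_horizontal(lm, ("1", "2"))
        np.testing.assert_allclose(out.points["2"], [1, 0], atol=1e-12)

    def test_axis_ends_horizontal_and_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            lm = _cloud(rng.uniform(-50, 50, size=(6, 2)))
            out = jl.rotate_to_horizontal(lm, ("1", "2"))
            v = out.points["2"] - out.points["1"]
            assert abs(v[1]) < 1e-9
            assert v[0] > 0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(point, min_size=3, max_size=8, unique=True))
    def test_isometry(self, coords):
        lm = _cloud(coords)
        a, b = lm.points["1"], lm.points["2"]
        if np.hypot(*(b - a)) < 1e-6:
            return
        out = jl.rotate_to_horizontal(lm, ("1", "2"))
        d0, d1 = _pairwise_distances(lm), _pairwise_distances(out)
        np.testing.assert_allclose(d1, d0, rtol=1e-9, atol=1e-9)

    def test_errors(self):
        lm = _cloud([(0, 0), (0, 0)])
        with pytest.raises(GeometryError, match="coincident"):
            jl.rotate_to_horizontal(lm, ("1", "2"))
        with pytest.raises(GeometryError, match="distinct"):
            jl.rotate_to_horizontal(lm, ("1", "1"))
        with pytest.raises(GeometryError, match="'99'"):
            jl.rotate_to_horizontal(lm, ("1", "99"))


class TestRotateJaw:
    def _jaw(self):
        return jl.LandmarkSet(
            points={"7": (0, 0), "9": (-5, 0), "4": (1, 8), "T1": (10, 0), "3": (8, -1)}
        )

    def test_zero_degrees_is_identity(self):
        lm = self._jaw()
        out = jl.rotate_jaw(lm, 0.0)
        for k in lm.points:
            np.testing.assert_allclose(out.points[k], lm.points[k])

    def test_closing_moves_tooth_dorsally(self):
        out = jl.rotate_jaw(self._jaw(), 90.0)
        np.testing.assert_allclose(out.points["T1"], [0, 10], atol=1e-12)

    def test_cranial_points_untouched(self):
        lm = self._jaw()
        out = jl.rotate_jaw(lm, 30.0)
        np.testing.assert_array_equal(out.points["4"], lm.points["4"])
        np.testing.assert_array_equal(out.points["9"], lm.points["9"])

    def test_round_trip(self):
        lm = jl.make_specimen(7).landmarks
        back = jl.rotate_jaw(jl.rotate_jaw(lm, 23.4), -23.4)
        for k in lm.points:
            np.testing.assert_allclose(back.points[k], lm.points[k], atol=1e-9)

    def test_large_angle_warns(self):
        with pytest.warns(UserWarning, match="physiological"):
            jl.rotate_jaw(self._jaw(), 150.0)

    def test_missing_pivot_errors(self):
        lm = jl.LandmarkSet(points={"2": (1, 1), "T1": (2, 0)})
        with pytest.raises(GeometryError, match="'7'"):
            jl.rotate_jaw(lm, 10.0)


class TestGapeToClosure:
    def test_collinear_is_zero(self):
        lm = jl.LandmarkSet(points={"7": (0, 0), "1": (10, 0), "2": (5, 0), "T1": (5, 0)})
        assert jl.compute_gape_to_closure(lm) == pytest.approx(0.0)

    def test_constructed_angle(self):
        a = math.radians(-20)
        lm = jl.LandmarkSet(
            points={"7": (0, 0), "1": (10, 0), "2": (10 * math.cos(a), 10 * math.sin(a)), "T1": (1, 1)}
        )
        assert jl.compute_gape_to_closure(lm) == pytest.approx(20.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_closing_by_computed_gape_closes(self, seed):
        lm = jl.make_specimen(seed, gape_deg=15.0).landmarks
        g = jl.compute_gape_to_closure(lm)
        closed = jl.rotate_jaw(lm, g)
        assert abs(jl.compute_gape_to_closure(closed)) < 1e-9

    def test_degenerate_errors(self):
        lm = jl.LandmarkSet(points={"7": (0, 0), "1": (0, 0), "2": (5, 0), "T1": (5, 0)})
        with pytest.raises(GeometryError, match="gape"):
            jl.compute_gape_to_closure(lm)


class TestLevers:
    def test_inlever_345(self):
        lm = jl.LandmarkSet(points={"7": (1, 1), "15": (4, 5)})
        assert jl.inlever(lm, "15") == pytest.approx(5.0)

    def test_scaling_homogeneity(self):
        lm = jl.LandmarkSet(points={"7": (1, 1), "15": (4, 5), "T1": (9, 7)})
        lm2 = jl.LandmarkSet(points={k: 2 * v for k, v in lm.points.items()})
        assert jl.inlever(lm2, "15") == pytest.approx(2 * jl.inlever(lm, "15"))
        np.testing.assert_allclose(jl.outlevers(lm2), 2 * jl.outlevers(lm))

    def test_outlever_5_12_13(self):
        lm = jl.LandmarkSet(points={"7": (0, 0), "T1": (12, 5)})
        np.testing.assert_allclose(jl.outlevers(lm), [13.0])

    def test_outlevers_match_bruteforce(self):
        rng = np.random.default_rng(3)
        pts = {"7": rng.uniform(-10, 10, 2)}
        for i in range(1, 8):
            pts[f"T{i}"] = rng.uniform(-10, 10, 2)
        lm = jl.LandmarkSet(points=pts)
        expected = [math.hypot(*(lm.points[f"T{i}"] - lm.points["7"])) for i in range(1, 8)]
        np.testing.assert_allclose(jl.outlevers(lm), expected, rtol=1e-12)

    def test_synthetic_outlevers_decrease(self, specimen):
        out = jl.outlevers(specimen.landmarks)
        assert np.all(np.diff(out) < 0)

    def test_levers_invariant_under_horizontalization(self, specimen):
        lm = specimen.landmarks
        lm2 = jl.rotate_to_horizontal(jl.LandmarkSet(
            points={k: v + np.array([3.0, -4.0]) for k, v in lm.points.items()}
        ))
        np.testing.assert_allclose(jl.outlevers(lm2), jl.outlevers(lm), rtol=1e-9)
        assert jl.inlever(lm2, "15") == pytest.approx(jl.inlever(lm, "15"), rel=1e-9)

    def test_zero_lever_errors(self):
        lm = jl.LandmarkSet(points={"7": (0, 0), "15": (0, 0), "T1": (0, 0)})
        with pytest.raises(GeometryError):
            jl.inlever(lm, "15")
        with pytest.raises(GeometryError):
            jl.outlevers(lm)


class TestAttachmentAngle:
    def test_perpendicular(self):
        lm = jl.LandmarkSet(points={"7": (0, 0), "15": (0, 5), "16": (-3, 5)})
        assert jl.attachment_angle(lm, "15", "16") == pytest.approx(90.0)

    def test_collinear_extremes(self):
        lm = jl.LandmarkSet(points={"7": (0, 0), "15": (0, 5), "16": (0, 9), "17": (0, 2)})
        assert jl.attachment_angle(lm, "15", "16") == pytest.approx(180.0)
        assert jl.attachment_angle(lm, "15", "17") == pytest.approx(0.0)

    def test_against_arccos_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            pts = {k: rng.uniform(-10, 10, 2) for k in ("7", "15", "16")}
            lm = jl.LandmarkSet(points=pts)
            v1 = lm.points["16"] - lm.points["15"]
            v2 = lm.points["7"] - lm.points["15"]
            if min(np.linalg.norm(v1), np.linalg.norm(v2)) < 1e-6:
                continue
            expect = math.degrees(
                math.acos(np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))
            )
            assert jl.attachment_angle(lm, "15", "16") == pytest.approx(expect, abs=1e-9)

    def test_angles_invariant_under_scaling(self, specimen):
        lm = specimen.landmarks
        lm2 = jl.LandmarkSet(points={k: 3 * v for k, v in lm.points.items()})
        assert jl.attachment_angle(lm2, "15", "16") == pytest.approx(
            jl.attachment_angle(lm, "15", "16"), abs=1e-9
        )


class TestFileFormats:
    def test_landmark_csv_round_trip(self, specimen):
        buf = io.StringIO()
        jl.write_landmarks_csv(specimen.landmarks, buf)
        buf.seek(0)
        lm = jl.read_landmarks_csv(buf)
        assert set(lm.points) == set(specimen.landmarks.points)
        for k in lm.points:
            np.testing.assert_allclose(lm.points[k], specimen.landmarks.points[k])

    def test_shapes_dialect(self):
        text = "7\n0.0\t0.0\nT1\n10.0\t2.0\n9\n-5.0 0.0\n"
        lm = jl.read_shapes_txt(io.StringIO(text), scale_mm_per_unit=2.0)
        np.testing.assert_allclose(lm.points["T1"], [20.0, 4.0])
        assert muscle_line_length(lm, "7", "9") == pytest.approx(10.0)

    def test_missing_column_errors(self):
        with pytest.raises(GeometryError, match="missing columns"):
            jl.read_landmarks_csv(io.StringIO("landmark_id,x\n1,0\n"))
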