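"""Muscle architecture, PCSA, force capacity and Hill scaling."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import jawlever as jl
from jawlever.muscles import MuscleError


def _muscle(**kw):
    base = dict(name="malaris_lateral", mass_g=10.0, pennation_deg=(0, 0, 0), tendon_length_mm=0.0)
    base.update(kw)
    return jl.MuscleArchitecture(**base)


class TestMuscleLength:
    def test_6_8_10(self):
        lm = jl.LandmarkSet(points={"7": (0, 0), "15": (1, 1), "16": (7, 9)})
        assert jl.muscle_length(lm, _muscle()) == pytest.approx(10.0)

    def test_invariant_under_rigid_rotation(self, specimen):
        lm = specimen.landmarks
        rotated = jl.rotate_to_horizontal(lm, ("5", "9"))
        for m in specimen.muscles:
            assert jl.muscle_length(rotated, m) == pytest.approx(
                jl.muscle_length(lm, m), rel=1e-9
            )

    def test_closing_shortens_adductors(self):
        sp = jl.make_specimen(5, gape_deg=15.0)
        lm_open = sp.landmarks
        for step in (5.0, 10.0, 15.0):
            lm_closed = jl.rotate_jaw(lm_open, step)
            for m in sp.muscles:
                assert jl.muscle_length(lm_closed, m) < jl.muscle_length(lm_open, m)

    def test_missing_landmark_names_muscle(self):
        lm = jl.LandmarkSet(points={"7": (0, 0), "15": (1, 1)})
        with pytest.raises(MuscleError, match="malaris_lateral.*'16'"):
            jl.muscle_length(lm, _muscle())


class TestFiberLengthAndPcsa:
    @pytest.mark.parametrize(
        "whole,tendon,expect", [(20.0, 5.0, 15.0), (7.0, 0.0, 7.0)]
    )
    def test_fiber_length(self, whole, tendon, expect):
        m = _muscle(tendon_length_mm=tendon)
        assert jl.fiber_length(m, whole) == pytest.approx(expect)

    def test_degenerate_fiber_errors(self):
        with pytest.raises(MuscleError, match="fiber"):
            jl.fiber_length(_muscle(tendon_length_mm=5.0), 5.0)

    def test_use_whole_flag(self):
        m = _muscle(tendon_length_mm=5.0)
        assert jl.fiber_length(m, 20.0, use_whole=True) == pytest.approx(20.0)

    def test_pcsa_hand_arithmetic(self):
        # 10 g, 2 cm fiber, 0 deg pennation, 1.06 g/cm^3 -> 4.717 cm^2
        m = _muscle(mass_g=10.0)
        assert jl.pcsa(m, 20.0) == pytest.approx(10.0 / (1.06 * 2.0), rel=1e-12)
        assert jl.pcsa(m, 20.0) == pytest.approx(4.717, abs=5e-4)

    def test_pcsa_cos_pennation(self):
        m = _muscle(mass_g=10.0, pennation_deg=(60, 60, 60))
        assert jl.pcsa(m, 20.0) == pytest.approx(4.717 / 2, abs=5e-4)

    def test_pcsa_90deg_is_zero_with_warning(self):
        m = _muscle(pennation_deg=(90, 90, 90))
        with pytest.warns(UserWarning, match="PCSA"):
            assert jl.pcsa(m, 20.0) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(
        mass=st.floats(0.01, 100, allow_nan=False),
        fiber=st.floats(1.0, 100, allow_nan=False),
        c=st.floats(1.1, 5.0, allow_nan=False),
    )
    def test_linear_in_mass_inverse_in_fiber(self, mass, fiber, c):
        m1, mc = _muscle(mass_g=mass), _muscle(mass_g=c * mass)
        assert jl.pcsa(mc, fiber) == pytest.approx(c * jl.pcsa(m1, fiber), rel=1e-9)
        assert jl.pcsa(m1, c * fiber) == pytest.approx(jl.pcsa(m1, fiber) / c, rel=1e-9)

    def test_pennation_mean_is_arithmetic(self):
        m = _muscle(pennation_deg=(10, 20, 60))
        assert m.mean_pennation_deg == pytest.approx(30.0)


class TestMaxForce:
    def test_unit_conversion(self):
        # 1 cm^2 at 300 kPa is exactly 30 N
        assert jl.max_muscle_force(1.0) == pytest.approx(30.0, rel=1e-12)

    def test_zero_area(self):
        assert jl.max_muscle_force(0.0) == 0.0

    def test_linear_in_specific_tension(self):
        hp = jl.HillParameters(specific_tension_kpa=600.0)
        assert jl.max_muscle_force(2.5, hp) == pytest.approx(2 * jl.max_muscle_force(2.5))

    def test_force_per_area_is_exactly_30(self):
        rng = np.random.default_rng(0)
        for a in rng.uniform(0.01, 50, 20):
            assert jl.max_muscle_force(a) / a == pytest.approx(30.0, rel=1e-12)


class TestHill:
    def test_printed_defaults(self):
        min_f, max_f = jl.hill_bounds()
        assert max_f == pytest.approx(0.79167, abs=5e-6)
        assert min_f == 0.0  # clamped
        raw_min, _ = jl.hill_bounds(jl.HillParameters(clamp_negative=False))
        assert raw_min == pytest.approx(-0.21212, abs=5e-6)

    def test_maxv_one_gives_zero_min(self):
        hp = jl.HillParameters(max_v=1.0, min_v=0.05, clamp_negative=False)
        assert jl.hill_bounds(hp)[0] == pytest.approx(0.0, abs=1e-15)

    def test_normalized_velocity_pins_open_jaw_at_zero(self):
        hp = jl.HillParameters(normalize_velocity=True, clamp_negative=False)
        min_f, max_f = jl.hill_bounds(hp)
        assert min_f == pytest.approx(0.0, abs=1e-15)
        assert 0 < max_f <= 1

    def test_activation_boundaries(self):
        hp = jl.HillParameters()
        min_f, max_f = jl.hill_bounds(hp)
        assert jl.activation_at_gape(0.0, 60.0, hp) == pytest.approx(max_f)
        assert jl.activation_at_gape(60.0, 60.0, hp) == pytest.approx(min_f)

    def test_activation_monotone_default_sweep(self):
        acts = [jl.activation_at_gape(g, 60.0) for g in np.linspace(0, 60, 61)]
        assert all(a1 >= a2 for a1, a2 in zip(acts, acts[1:]))

    @settings(derandomize=True, max_examples=200)
    @given(
        k=st.floats(0.01, 5, allow_nan=False),
        min_v=st.floats(0.001, 1.0, allow_nan=False),
        span=st.floats(0.01, 20, allow_nan=False),
        norm=st.booleans(),
    )
    def test_activation_monotone_and_bounded(self, k, min_v, span, norm):
        hp = jl.HillParameters(k=k, min_v=min_v, max_v=min_v + span, normalize_velocity=norm)
        min_f, max_f = jl.hill_bounds(hp)
        gapes = np.linspace(0, 45.0, 31)
        acts = [jl.activation_at_gape(g, 45.0, hp) for g in gapes]
        assert all(a1 >= a2 - 1e-12 for a1, a2 in zip(acts, acts[1:]))
        for a in acts:
            assert min_f - 1e-12 <= a <= max_f + 1e-12

    def test_gape_out_of_range_errors(self):
        with pytest.raises(MuscleError, match="gape"):
            jl.activation_at_gape(70.0, 60.0)
        with pytest.raises(MuscleError, match="gape"):
            jl.activation_at_gape(-1.0, 60.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(MuscleError):
            jl.HillParameters(max_v=0.01, min_v=0.05)
        with pytest.raises(MuscleError):
            jl.HillParameters(k=0.0)


class TestMuscleCsv:
    def test_round_trip(self, specimen):
        buf = io.StringIO()
        jl.write_muscles_csv(specimen.muscles, buf, specimen_id="s1")
        buf.seek(0)
        muscles = jl.read_muscles_csv(buf)
        assert [m.name for m in muscles] == [m.name for m in specimen.muscles]
        for a, b in zip(muscles, specimen.muscles):
            assert a.mass_g == pytest.approx(b.mass_g)
            assert a.pennation_deg == pytest.approx(b.pennation_deg)
            assert (a.insertion_id, a.origin_id) == (b.insertion_id, b.origin_id)

    def test_default_attachments_fill_in(self):
        csv = (
            "specimen_id,muscle,mass_g,penn_dorsal,penn_inline,penn_ventral,tendon_mm\n"
            "s1,stegalis,1.0,10,12,14,2.0\n"
        )
        (m,) = jl.read_muscles_csv(io.StringIO(csv))
        assert (m.insertion_id, m.origin_id) == ("18", "19")

    def test_bad_mass_rejected(self):
        with pytest.raises(MuscleError, match="mass"):
            _muscle(mass_g=-1.0)
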