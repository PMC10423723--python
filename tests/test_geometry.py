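"""Stimulus geometry: disparity quantum, placement, distance solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereovr.errors import (
    GeometryInfeasibleError,
    InvalidConfigError,
    NotRenderableError,
)
from stereovr.geometry import (
    ARCSEC_TO_RAD,
    PERIPHERAL_LABELS,
    POSITION_LABELS,
    HeadsetSpec,
    build_trial_schedule,
    disparity_of_far_object,
    jitter_ball_offsets,
    min_disparity_difference,
    quantize_disparity,
    recovered_disparity_arcsec,
    size_scale,
    solve_target_distance,
    stimulus_position,
)


class TestDisparityQuantum:
    @pytest.mark.parametrize(
        "fov,px,expected",
        [(110.0, 1440, 275.0), (107.0, 1440, 267.5), (90.0, 1000, 324.0)],
    )
    def test_pixel_quantum(self, fov, px, expected):
        assert min_disparity_difference(HeadsetSpec(fov_deg=fov, h_pixels=px)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_invalid_headset_rejected(self):
        for bad in (dict(fov_deg=0), dict(h_pixels=0), dict(ipd_cm=-1), dict(refresh_hz=0)):
            with pytest.raises(InvalidConfigError):
                HeadsetSpec(**bad)

    @pytest.mark.parametrize("requested,expected", [(275.0, 275.0), (550.0, 550.0), (300.0, 275.0)])
    def test_quantize_to_nearest_multiple(self, requested, expected):
        assert quantize_disparity(requested, HeadsetSpec()) == expected

    def test_quantize_rejects_unrenderable(self):
        with pytest.raises(NotRenderableError):
            quantize_disparity(100.0, HeadsetSpec())  # below half the 275″ quantum
        with pytest.raises(NotRenderableError):
            quantize_disparity(-5.0, HeadsetSpec())


class TestPlacement:
    def test_central_position(self):
        for formula in ("printed", "corrected"):
            np.testing.assert_allclose(
                stimulus_position(200.0, 0.0, 0.0, formula), [200.0, 0.0, 0.0]
            )

    def test_formulas_agree_in_sagittal_plane(self):
        # φ = 0 collapses both variants to r·(cosθ, 0, −sinθ)
        expected = 200.0 * np.array([math.cos(math.radians(10)), 0.0, -math.sin(math.radians(10))])
        for formula in ("printed", "corrected"):
            np.testing.assert_allclose(stimulus_position(200.0, 10.0, 0.0, formula), expected)

    def test_corrected_preserves_radius_everywhere(self):
        for phi in range(0, 360, 45):
            p = stimulus_position(200.0, 10.0, float(phi), "corrected")
            assert abs(np.linalg.norm(p) - 200.0) < 1e-9

    def test_printed_formula_verbatim(self):
        th, ph = math.radians(10.0), math.radians(90.0)
        expected = 200.0 * np.array(
            [math.cos(th), math.sin(ph) * math.cos(th), -math.cos(ph) * math.sin(th)]
        )
        np.testing.assert_allclose(stimulus_position(200.0, 10.0, 90.0, "printed"), expected)
        # at φ=90° the printed variant inflates the radius to 200·√2·cosθ
        assert np.linalg.norm(expected) == pytest.approx(200.0 * math.sqrt(2) * math.cos(th))


class TestDistanceSolver:
    def test_far_disparity_value(self):
        phi_b = disparity_of_far_object(6.3, 200.0)
        assert phi_b == pytest.approx(2 * math.atan(6.3 / 400.0), abs=1e-15)
        # small-angle approximation within 0.05 %
        assert phi_b == pytest.approx(6.3 / 200.0, rel=5e-4)
        assert disparity_of_far_object(0.0, 200.0) == 0.0

    @staticmethod
    def _bisection_oracle(theta_arcsec, ipd=6.3, d_total=200.0, e=0.0):
        """Independent root-finder on f(D) = Φ_A(D) − Φ_B − Θ."""
        phi_b = 2 * math.atan(ipd / (2 * d_total))
        theta = theta_arcsec * ARCSEC_TO_RAD
        l1, l2 = abs(e), abs(e) + ipd

        def f(D):
            return (math.atan(l2 / D) - math.atan(l1 / D)) - phi_b - theta

        lo, hi = 1e-6, d_total
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    @pytest.mark.parametrize("theta", [275.0, 550.0, 1100.0])
    @pytest.mark.parametrize("e", [0.0, 12.5])
    def test_quadratic_matches_bisection(self, theta, e):
        sol = solve_target_distance(theta, 6.3, 200.0, e)
        assert sol.D_cm == pytest.approx(self._bisection_oracle(theta, e=e), abs=1e-6)

    def test_known_distance_at_hardest_disparity(self):
        assert solve_target_distance(275.0).D_cm == pytest.approx(191.825, abs=1e-3)

    def test_distance_monotone_in_disparity(self):
        ds = [solve_target_distance(275.0 * k).D_cm for k in range(1, 21)]
        assert all(a > b for a, b in zip(ds, ds[1:]))
        assert all(0 < d < 200.0 for d in ds)

    @pytest.mark.parametrize("k", range(1, 21))
    def test_round_trip_recovers_disparity(self, k):
        theta = 275.0 * k
        sol = solve_target_distance(theta)
        assert recovered_disparity_arcsec(sol) == pytest.approx(theta, abs=0.5)

    def test_solution_invariants(self):
        sol = solve_target_distance(550.0, 6.3, 200.0, 5.0)
        assert sol.l2_cm == sol.l1_cm + 6.3
        assert sol.c2 == sol.l1_cm - sol.l2_cm
        assert 0 < sol.scale_s <= 1

    def test_overflow_disparity_rejected(self):
        with pytest.raises((GeometryInfeasibleError, Exception)):
            solve_target_distance(90.5 * 3600.0)  # Θ+Φ_B past 90°

    @pytest.mark.parametrize("d,total,expected", [(100.0, 200.0, 0.5), (200.0, 200.0, 1.0)])
    def test_size_scale(self, d, total, expected):
        assert size_scale(d, total) == expected

    def test_size_scale_domain(self):
        with pytest.raises(InvalidConfigError):
            size_scale(250.0, 200.0)
        with pytest.raises(InvalidConfigError):
            size_scale(0.0, 200.0)


class TestJitter:
    def test_bounds_and_determinism(self):
        a = jitter_ball_offsets(42)
        b = jitter_ball_offsets(42)
        assert a == b
        assert set(a) == {"Up", "Down", "Left", "Right"}
        assert all(-2.0 <= v <= 2.0 for v in a.values())

    def test_mean_magnitude_matches_uniform_model(self):
        rng = np.random.default_rng(7)
        mags = [abs(v) for _ in range(2500) for v in jitter_ball_offsets(rng).values()]
        assert np.mean(mags) == pytest.approx(1.0, abs=0.05)


class TestSchedule:
    def test_default_design_has_81_stimuli(self):
        sched = build_trial_schedule(seed=0)
        assert len(sched) == 81

    def test_cell_counts(self):
        sched = build_trial_schedule(seed=1)
        from collections import Counter

        counts = Counter((s.disparity_arcsec, s.position_label) for s in sched.stimuli)
        assert len(counts) == 27
        assert set(counts.values()) == {3}

    def test_minimal_design(self):
        sched = build_trial_schedule(disparities=(275.0,), positions=("Central",), repetitions=1)
        assert len(sched) == 1
        assert sched.stimuli[0].position_label == "Central"
        assert sched.stimuli[0].inclination_deg == 0.0

    def test_all_disparities_on_pixel_grid(self):
        sched = build_trial_schedule(seed=5)
        dd = min_disparity_difference(HeadsetSpec())
        for s in sched.stimuli:
            assert s.disparity_arcsec % dd == 0

    def test_seed_determinism_and_variation(self):
        a = build_trial_schedule(seed=9)
        b = build_trial_schedule(seed=9)
        c = build_trial_schedule(seed=10)
        assert [s.disparity_arcsec for s in a.stimuli] == [s.disparity_arcsec for s in b.stimuli]
        assert [s.target_ball for s in a.stimuli] == [s.target_ball for s in b.stimuli]
        assert [s.disparity_arcsec for s in a.stimuli] != [s.disparity_arcsec for s in c.stimuli]

    def test_peripheral_angles(self):
        sched = build_trial_schedule(seed=2)
        for s in sched.stimuli:
            if s.position_label == "Central":
                assert s.azimuth_deg == 0.0 and s.inclination_deg == 0.0
            else:
                assert s.inclination_deg == 10.0
                assert s.azimuth_deg == 45.0 * PERIPHERAL_LABELS.index(s.position_label)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_schedule_is_permutation_of_factorial_design(self, seed):
        sched = build_trial_schedule(seed=seed)
        assert sorted(
            (s.disparity_arcsec, s.position_label) for s in sched.stimuli
        ) == sorted((d, p) for d in (275.0, 550.0, 1100.0) for p in POSITION_LABELS for _ in range(3))
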