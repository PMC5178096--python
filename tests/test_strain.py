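"""Strain/motion curves, rates, phase detection and phasic indices."""

import numpy as np
import pytest

from lastrain.errors import InvalidInputError, PhaseDetectionError
from lastrain.geometry import Contour, ContourSequence, center_of_mass, segment_radii
from lastrain.phantoms import LAMotionParams, make_la_phantom
from lastrain.pipeline import analyze_la_views
from lastrain.strain import (
    PhaseBoundaries,
    StrainCurves,
    detect_phases,
    global_average,
    longitudinal_strain_curve,
    phasic_indices,
    radial_motion_curve,
    rate_curve,
)

from conftest import circle_contour, random_polyline, sequence_of_scalings


def _times(n, cycle=1000.0):
    return np.linspace(0.0, cycle, n)


class TestLongitudinalStrain:
    def test_circle_dilation_gives_perimeter_ratio(self):
        # r 30 -> 36 mm: perimeter scales with radius, sl = 0.20
        frames = tuple(
            circle_contour(radius=30.0 * (1 + 0.2 * k / 9), n=180) for k in range(10)
        )
        seq = ContourSequence(frames=frames, times=_times(10), view="4-chamber")
        sl = longitudinal_strain_curve(seq)
        assert sl[0] == 0.0
        assert sl[-1] == pytest.approx(0.20, abs=1e-12)

    def test_rigid_translation_zero_strain(self, rng):
        base = random_polyline(rng, n=40)
        frames = tuple(
            Contour(points=base.points + [3.0 * k, -2.0 * k], closed=False) for k in range(12)
        )
        seq = ContourSequence(frames=frames, times=_times(12), view="2-chamber")
        np.testing.assert_allclose(longitudinal_strain_curve(seq), 0.0, atol=1e-12)

    def test_ellipse_matches_numeric_perimeter_oracle(self):
        def ellipse(a, b, n):
            t = np.linspace(0, 2 * np.pi, n, endpoint=False)
            return Contour(points=np.column_stack([a * np.cos(t), b * np.sin(t)]), closed=True)

        def perimeter_oracle(a, b):
            t = np.linspace(0, 2 * np.pi, 100_000)
            return np.trapezoid(np.hypot(a * np.sin(t), b * np.cos(t)), t)

        n = 2000
        frames = tuple([ellipse(20, 30, n)] * 9 + [ellipse(24, 33, n)])
        seq = ContourSequence(frames=frames, times=_times(10), view="3-chamber")
        sl = longitudinal_strain_curve(seq)
        expected = perimeter_oracle(24, 33) / perimeter_oracle(20, 30) - 1.0
        assert sl[-1] == pytest.approx(expected, rel=1e-5)


class TestRadialMotion:
    def test_uniform_scaling_recovered_exactly(self, rng):
        scales = np.array([0.0, 0.05, 0.15, 0.332, 0.25, 0.167, 0.1, 0.05, 0.02, 0.0])
        seq = sequence_of_scalings(random_polyline(rng, n=60), scales)
        mr = radial_motion_curve(seq)
        np.testing.assert_allclose(mr, scales, atol=1e-9)

    def test_no_motion_zero_everywhere(self, rng):
        seq = sequence_of_scalings(random_polyline(rng, n=40), np.zeros(10))
        np.testing.assert_allclose(radial_motion_curve(seq), 0.0, atol=1e-12)

    def test_anisotropic_scaling_matches_bruteforce_segments(self):
        base = circle_contour(radius=20.0, n=120)
        sx, sy = 0.9, 0.7
        squeezed = Contour(points=base.points * [sx, sy], closed=True)
        frames = tuple([base] * 9 + [squeezed])
        seq = ContourSequence(frames=frames, times=_times(10), view="4-chamber")
        mr = radial_motion_curve(seq, n_segments=12, grid_points=120)
        # brute-force oracle: same definition computed point-by-point here
        c0 = center_of_mass(base)
        r0 = segment_radii(base, c0, 12, 120)
        r1 = segment_radii(squeezed, c0, 12, 120)
        oracle = np.mean((r1 - r0) / r0)
        assert mr[-1] == pytest.approx(oracle, abs=1e-12)
        assert mr[-1] < 0  # net shrinkage


class TestRateCurve:
    def test_linear_ramp_constant_rate(self):
        t = _times(20)
        sl = 0.3 * t / t[-1]
        np.testing.assert_allclose(rate_curve(sl, t), 0.3 / (t[-1] / 1000.0), atol=1e-9)

    def test_constant_series_zero(self):
        t = _times(15)
        np.testing.assert_allclose(rate_curve(np.full(15, 0.2), t), 0.0, atol=1e-15)

    def test_sine_against_analytic_cosine(self):
        n = 200
        t_s = np.linspace(0, 2 * np.pi, n)
        sl = np.sin(t_s)
        deriv = rate_curve(sl, t_s * 1000.0)
        h = 2 * np.pi / n
        interior_err = np.abs(deriv[1:-1] - np.cos(t_s[1:-1]))
        assert interior_err.max() < h**2
        edge_err = np.abs(deriv[[0, -1]] - np.cos(t_s[[0, -1]]))
        assert edge_err.max() < h

    def test_integrating_rate_recovers_net_strain(self):
        seqs, _ = make_la_phantom(LAMotionParams())
        seq = seqs["4-chamber"]
        sl = longitudinal_strain_curve(seq)
        srl = rate_curve(sl, seq.times)
        integral = np.trapezoid(srl, seq.times / 1000.0)
        assert integral == pytest.approx(sl[-1] - sl[0], abs=5e-3)

    def test_non_monotonic_times_rejected(self):
        with pytest.raises(InvalidInputError):
            rate_curve(np.arange(5.0), np.array([0.0, 1.0, 1.0, 2.0, 3.0]))


class TestDetectPhases:
    def test_piecewise_linear_breakpoints_recovered(self):
        # rise to 33% at 40% cycle, fall to 17% at 75%, fall to 0
        t = _times(21)
        sl = np.interp(t, [0, 400, 750, 1000], [0, 0.33, 0.17, 0.0])
        phases = detect_phases(sl, t)
        assert abs(phases.t_peak - 400.0) <= 50.0 + 1e-9
        assert abs(phases.t_a_onset - 750.0) <= 50.0 + 1e-9

    def test_phantom_truth_within_one_frame(self):
        params = LAMotionParams()
        seqs, truth = make_la_phantom(params)
        seq = seqs["4-chamber"]
        sl = longitudinal_strain_curve(seq)
        phases = detect_phases(sl, seq.times)
        frame_ms = seq.times[1] - seq.times[0]
        assert abs(phases.t_peak - truth["t_peak_ms"]) <= frame_ms + 1e-9
        assert abs(phases.t_a_onset - truth["t_a_onset_ms"]) <= frame_ms + 1e-9

    def test_flat_curve_fails(self):
        with pytest.raises(PhaseDetectionError):
            detect_phases(np.zeros(20), _times(20))

    def test_monotonic_curve_fails(self):
        t = _times(20)
        with pytest.raises(PhaseDetectionError):
            detect_phases(t / t[-1], t)

    def test_explicit_override(self):
        t = _times(21)
        sl = np.interp(t, [0, 400, 750, 1000], [0, 0.33, 0.17, 0.0])
        phases = detect_phases(sl, t, a_onset_override=700.0)
        assert phases.t_a_onset == 700.0


def _curves_from_series(t, sl):
    return StrainCurves(times=t, sl=sl, mr=sl.copy(), srl=rate_curve(sl, t), vr=rate_curve(sl, t))


class TestPhasicIndices:
    def test_table_scale_curve(self):
        # peak 33.2%, pre-contraction 16.7%, back to 0: R/C/A = 33.2/16.5/16.7
        t = _times(21)
        sl = np.interp(t, [0, 400, 750, 1000], [0, 0.332, 0.167, 0.0])
        idx = phasic_indices(_curves_from_series(t, sl), PhaseBoundaries(400.0, 750.0, 1000.0))
        assert idx.sl_r == pytest.approx(33.2)
        assert idx.sl_a == pytest.approx(16.7)
        assert idx.sl_c == pytest.approx(16.5)

    def test_symmetric_triangle_half_ratio(self):
        t = _times(21)
        sl = np.interp(t, [0, 500, 750, 1000], [0, 0.3, 0.15, 0.0])
        idx = phasic_indices(_curves_from_series(t, sl), PhaseBoundaries(500.0, 750.0, 1000.0))
        assert idx.sl_c == pytest.approx(idx.sl_a)
        assert idx.sl_a_over_sl_r == pytest.approx(0.5)

    def test_additivity_exact_on_computed_curves(self, rng):
        for _ in range(5):
            params = LAMotionParams(
                sl_r_true=float(rng.uniform(15, 45)),
                sl_a_true=float(rng.uniform(5, 14)),
                seed=int(rng.integers(2**31)),
                noise_sd_mm=0.3,
            )
            seqs, _ = make_la_phantom(params)
            g, per_view, _ = analyze_la_views(seqs)
            for idx in (g, *per_view.values()):
                assert idx.sl_r == pytest.approx(idx.sl_c + idx.sl_a, abs=1e-9)
                assert idx.mr_r == pytest.approx(idx.mr_c + idx.mr_a, abs=1e-9)

    def test_phantom_recovery_within_2pct(self):
        seqs, truth = make_la_phantom(LAMotionParams())
        g, _, _ = analyze_la_views(seqs)
        for key in ("sl_r", "sl_c", "sl_a", "mr_r", "mr_c", "mr_a"):
            assert getattr(g, key) == pytest.approx(truth[key], rel=0.02)

    def test_rate_peaks_recover_analytic_truth_loosely(self):
        # finite differences + smoothing on a 20-phase cine: 25% band
        seqs, truth = make_la_phantom(LAMotionParams())
        g, _, _ = analyze_la_views(seqs)
        for key in ("srl_s", "srl_e", "srl_a"):
            assert getattr(g, key) == pytest.approx(truth[key], rel=0.25)
        assert g.srl_e < 0 and g.srl_a < 0 and g.srl_s > 0


class TestTimeDilationInvariance:
    def test_strain_unchanged_rates_scaled(self):
        p_fast = LAMotionParams(cycle_ms=800.0)
        p_slow = LAMotionParams(cycle_ms=1200.0)
        g_fast, _, _ = analyze_la_views(make_la_phantom(p_fast)[0])
        g_slow, _, _ = analyze_la_views(make_la_phantom(p_slow)[0])
        for key in ("sl_r", "sl_c", "sl_a", "mr_r", "mr_c", "mr_a"):
            assert getattr(g_fast, key) == pytest.approx(getattr(g_slow, key), rel=1e-9)
        for key in ("srl_s", "srl_e", "srl_a", "vr_s", "vr_e", "vr_a"):
            assert getattr(g_fast, key) * 800.0 == pytest.approx(
                getattr(g_slow, key) * 1200.0, rel=1e-9
            )


class TestGlobalAverage:
    def test_identical_views_unchanged(self):
        seqs, _ = make_la_phantom(LAMotionParams())
        _, per_view, _ = analyze_la_views(seqs)
        one = per_view["4-chamber"]
        avg = global_average([one, one, one])
        for k, v in one.as_dict().items():
            assert avg.as_dict()[k] == pytest.approx(v, abs=1e-12)

    def test_two_views_arithmetic_mean(self):
        seqs, _ = make_la_phantom(LAMotionParams())
        _, per_view, _ = analyze_la_views(seqs)
        a, b = per_view["2-chamber"], per_view["3-chamber"]
        avg = global_average([a, b])
        assert avg.sl_r == pytest.approx((a.sl_r + b.sl_r) / 2)

    def test_three_views_match_independent_mean(self):
        seqs, _ = make_la_phantom(LAMotionParams())
        g, per_view, _ = analyze_la_views(seqs)
        assert g.mr_r == pytest.approx(np.mean([p.mr_r for p in per_view.values()]))

    def test_ratio_fields_recomputed_from_averages(self):
        seqs, _ = make_la_phantom(LAMotionParams())
        g, per_view, _ = analyze_la_views(seqs)
        assert g.sl_a_over_sl_r == pytest.approx(g.sl_a / g.sl_r)
        assert g.srl_e_over_a == pytest.approx(abs(g.srl_e) / abs(g.srl_a))

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            global_average([])


def test_too_few_frames_rejected(rng):
    base = random_polyline(rng, n=30)
    with pytest.raises(InvalidInputError):
        ContourSequence(frames=tuple([base] * 5), times=np.linspace(0, 1000, 5))
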