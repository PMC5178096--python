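"""MV-referenced decomposition of radial motion: cMr / pMr."""

import numpy as np
import pytest

from lastrain.decomposition import decompose_radial, decomposed_phasic, mv_geometry
from lastrain.errors import DegenerateAxisError, MissingLandmarkError
from lastrain.geometry import Contour, ContourSequence, center_of_mass
from lastrain.phantoms import LAMotionParams, control_decomposition_params, make_la_phantom
from lastrain.strain import PhaseBoundaries


def _arc(n=120, radius=30.0, rot_deg=0.0):
    """Open circular arc with a bottom gap; endpoints are the MV landmarks."""
    gap = np.deg2rad(20.0)
    theta = np.linspace(-np.pi / 2 + gap, 3 * np.pi / 2 - gap, n)
    pts = np.column_stack([radius * np.cos(theta), -radius * np.sin(theta)])
    phi = np.deg2rad(rot_deg)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    return pts @ rot.T


def _seq_from_frames(frame_points, cycle=1000.0, view="4-chamber"):
    frames = tuple(Contour(points=p, closed=False) for p in frame_points)
    mv = np.array([[p[0], p[-1]] for p in frame_points])
    times = np.linspace(0.0, cycle, len(frames))
    return ContourSequence(frames=frames, times=times, view=view, mv_points=mv)


class TestMVGeometry:
    def test_midpoint_and_axis(self):
        # landmarks (-10,0) and (10,0) with the LA body arched above them:
        # mv_center is the origin and the axis points straight down at it
        theta = np.linspace(np.pi, 0, 100)
        pts = np.column_stack([10 * np.cos(theta), 30 * np.sin(theta)])
        seq = _seq_from_frames([pts] * 10)
        geom = mv_geometry(seq)
        np.testing.assert_allclose(geom.mv_center, [0.0, 0.0], atol=1e-9)
        com = center_of_mass(seq.frames[0])
        assert com[1] > 0
        np.testing.assert_allclose(geom.mv_axis, [0.0, -1.0], atol=1e-9)

    def test_missing_landmarks(self):
        frames = tuple(Contour(points=_arc()) for _ in range(10))
        seq = ContourSequence(frames=frames, times=np.linspace(0, 1000, 10))
        with pytest.raises(MissingLandmarkError):
            mv_geometry(seq)

    def test_rotation_equivariance(self):
        seq0 = _seq_from_frames([_arc(rot_deg=0.0)] * 10)
        seq1 = _seq_from_frames([_arc(rot_deg=35.0)] * 10)
        g0, g1 = mv_geometry(seq0), mv_geometry(seq1)
        phi = np.deg2rad(35.0)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        np.testing.assert_allclose(g1.mv_axis, rot @ g0.mv_axis, atol=1e-9)

    def test_degenerate_axis_rejected(self):
        # full circle: centroid == landmark midpoint when landmarks are
        # placed symmetrically through the centre
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([30 * np.cos(theta), 30 * np.sin(theta)])
        frames = tuple(Contour(points=pts, closed=False) for _ in range(10))
        mv = np.array([[[30.0, 0.0], [-30.0, 0.0]]] * 10)
        seq = ContourSequence(frames=frames, times=np.linspace(0, 1000, 10), mv_points=mv)
        with pytest.raises(DegenerateAxisError):
            mv_geometry(seq)


class TestDecomposeRadial:
    def test_translation_along_axis_pure_cmr(self):
        p0 = _arc()
        geom_seq = _seq_from_frames([p0] * 10)
        geom = mv_geometry(geom_seq)
        d = 4.0
        shifts = np.linspace(0, d, 10)
        seq = _seq_from_frames([p0 + s * geom.mv_axis for s in shifts])
        cmr, pmr = decompose_radial(seq, geom)
        np.testing.assert_allclose(pmr, 0.0, atol=1e-12)
        # per-segment |d| / M0 averaged over segments
        c0 = center_of_mass(seq.frames[0])
        seg_p0 = seq.resampled(120).frames[0].points.reshape(12, -1, 2).mean(axis=1)
        m0 = np.linalg.norm(seg_p0 - c0, axis=1)
        assert cmr[-1] == pytest.approx(d * np.mean(1.0 / m0), abs=1e-12)
        # circular arc: segment radii are nearly equal, so this is close to
        # translation over mean radius
        assert cmr[-1] == pytest.approx(d / m0.mean(), rel=0.02)

    def test_translation_across_axis_pure_pmr(self):
        p0 = _arc()
        geom = mv_geometry(_seq_from_frames([p0] * 10))
        perp = geom.mv_perp
        seq = _seq_from_frames([p0 + s * perp for s in np.linspace(0, 5, 10)])
        cmr, pmr = decompose_radial(seq, geom)
        np.testing.assert_allclose(cmr, 0.0, atol=1e-12)
        assert pmr[-1] > 0

    def test_recombination_identity(self, rng):
        # squared centric + squared perpendicular == squared displacement,
        # per segment and frame, on a deforming + translating phantom
        seqs, _ = make_la_phantom(
            LAMotionParams(translation_along_mm=3.0, translation_across_mm=5.0,
                           noise_sd_mm=0.5, seed=11)
        )
        for seq in seqs.values():
            geom = mv_geometry(seq)
            cmr, pmr, du, dv, disp = decompose_radial(
                seq, geom, return_segment_displacements=True
            )
            total_sq = np.sum(disp**2, axis=2)
            recombined = du**2 + dv**2
            np.testing.assert_allclose(recombined, total_sq, rtol=1e-12, atol=1e-18)

    def test_rotation_leaves_cmr_pmr_unchanged(self):
        params = LAMotionParams(translation_along_mm=2.0, translation_across_mm=4.0)
        seqs, _ = make_la_phantom(params)
        seq = seqs["4-chamber"]
        phi = np.deg2rad(27.0)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        rotated = ContourSequence(
            frames=tuple(Contour(points=f.points @ rot.T, closed=False) for f in seq.frames),
            times=seq.times,
            view=seq.view,
            mv_points=seq.mv_points @ rot.T,
        )
        c0, p0 = decompose_radial(seq, mv_geometry(seq))
        c1, p1 = decompose_radial(rotated, mv_geometry(rotated))
        np.testing.assert_allclose(c1, c0, atol=1e-9)
        np.testing.assert_allclose(p1, p0, atol=1e-9)

    def test_independent_perpoint_oracle_on_known_motion(self):
        # isotropic contraction about the reference centroid + axial shift:
        # closed-form projections computed per point here, independently
        p0 = _arc()
        ref_seq = _seq_from_frames([p0] * 10)
        geom = mv_geometry(ref_seq)
        c0 = center_of_mass(ref_seq.frames[0])
        s_amp, d_amp = -0.1, 3.0
        frames = []
        for k in range(10):
            a = k / 9.0
            frames.append(c0 + (1 + a * s_amp) * (p0 - c0) + a * d_amp * geom.mv_axis)
        seq = _seq_from_frames(frames)
        cmr, pmr = decompose_radial(seq, geom, n_segments=12, grid_points=120)
        # oracle
        u, v = geom.mv_axis, np.array([-geom.mv_axis[1], geom.mv_axis[0]])
        seg0 = p0.reshape(12, -1, 2).mean(axis=1)
        m0 = np.linalg.norm(seg0 - c0, axis=1)
        d_last = (seg0 - c0) * s_amp + d_amp * u
        assert cmr[-1] == pytest.approx(np.mean(np.abs(d_last @ u) / m0), abs=1e-9)
        assert pmr[-1] == pytest.approx(np.mean(np.abs(d_last @ v) / m0), abs=1e-9)


class TestDecomposedPhasic:
    def test_cmr_equals_mr_when_pmr_zero(self):
        t = np.linspace(0, 1000, 21)
        mr = np.interp(t, [0, 400, 750, 1000], [0, 0.35, 0.18, 0.0])
        out = decomposed_phasic(mr, np.zeros_like(mr), t, PhaseBoundaries(400, 750, 1000))
        assert out["cmr_r"] == pytest.approx(35.0)
        assert out["cmr_a"] == pytest.approx(18.0)
        assert out["cmr_c"] == pytest.approx(17.0)
        assert out["pmr_r"] == out["pmr_c"] == out["pmr_a"] == 0.0

    def test_control_scale_phantom_reproduces_published_control_means(self):
        from lastrain.pipeline import analyze_la_views

        seqs, _ = make_la_phantom(control_decomposition_params())
        g, _, _ = analyze_la_views(seqs)
        assert g.cmr_a == pytest.approx(20.3, abs=0.5)
        assert g.pmr_r == pytest.approx(53.3, abs=0.5)

    def test_phantom_additivity(self):
        from lastrain.pipeline import analyze_la_views

        seqs, _ = make_la_phantom(
            LAMotionParams(translation_along_mm=6.0, translation_across_mm=9.0)
        )
        g, _, _ = analyze_la_views(seqs)
        assert g.cmr_r == pytest.approx(g.cmr_c + g.cmr_a, abs=1e-9)
        assert g.pmr_r == pytest.approx(g.pmr_c + g.pmr_a, abs=1e-9)
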