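"""Mitral-valve-referenced decomposition of LA radial motion.

Radial motion of the atrial wall mixes two things: intrinsic atrial
deformation and bulk displacement of the atrium dragged by the ventricle
through the mitral annulus. To separate them, each wall segment's
displacement from its reference position is resolved into two orthogonal
components in the image plane:

* **centric (cMr)** — along the axis from the LA centre of mass toward the
  mitral-valve centre (intrinsic, atrio-ventricular-directed motion);
* **perpendicular (pMr)** — normal to that axis, which broadly carries the
  ventricular translational motion.

The geometry (MV centre, axis) is frozen at the reference frame: the
decomposition needs a fixed external reference, otherwise per-frame
re-estimation would absorb the very translation it is meant to expose.

Per segment the two projected displacement magnitudes are normalised by the
same reference radius M0 used for Mr, so cMr and pMr are commensurate with
Mr; note cMr + pMr != Mr in general (orthogonal components of the
displacement vector versus its radial component). The tested contract is the
exact recombination (d.u)^2 + (d.v)^2 = |d|^2 per segment and frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateAxisError, InvalidInputError, MissingLandmarkError
from .geometry import DEFAULT_GRID_POINTS, DEFAULT_N_SEGMENTS, ContourSequence, center_of_mass
from .strain import PhaseBoundaries, PhasicIndices, _at


@dataclass(frozen=True)
class MVFrameGeometry:
    """Reference-frame mitral-valve geometry.

    ``mv_center`` is the midpoint of the two annulus landmarks; ``mv_axis``
    the unit vector from the LA reference centre of mass toward it.
    """

    mv_center: np.ndarray
    mv_axis: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.mv_center, dtype=float)
        a = np.asarray(self.mv_axis, dtype=float)
        if not np.all(np.isfinite(c)):
            raise InvalidInputError("mv_center must be finite")
        if abs(np.linalg.norm(a) - 1.0) > 1e-9:
            raise InvalidInputError("mv_axis must be a unit vector")
        object.__setattr__(self, "mv_center", c)
        object.__setattr__(self, "mv_axis", a)

    @property
    def mv_perp(self) -> np.ndarray:
        """Unit vector orthogonal to the MV axis (90 degrees CCW)."""
        return np.array([-self.mv_axis[1], self.mv_axis[0]])


def mv_geometry(seq: ContourSequence) -> MVFrameGeometry:
    """MV centre and axis from the reference frame of a contour sequence."""
    if seq.mv_points is None:
        raise MissingLandmarkError(f"no mitral annulus landmarks on {seq.view} sequence")
    landmarks = seq.mv_points[0]
    mv_center = landmarks.mean(axis=0)
    la_center = center_of_mass(seq.frames[0])
    d = mv_center - la_center
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise DegenerateAxisError("LA centre of mass coincides with the MV centre; axis undefined")
    return MVFrameGeometry(mv_center=mv_center, mv_axis=d / norm)


def decompose_radial(
    seq: ContourSequence,
    geom: MVFrameGeometry,
    n_segments: int = DEFAULT_N_SEGMENTS,
    grid_points: int = DEFAULT_GRID_POINTS,
    return_segment_displacements: bool = False,
):
    """cMr(t) and pMr(t) series (dimensionless, 0 at the reference frame).

    Every frame is resampled to ``grid_points`` so points correspond by
    arc-length index. Per frame, each segment's mean displacement vector d
    from its reference position is projected on the MV axis u and its normal
    v; |d.u| / M0 and |d.v| / M0 (M0 the segment's reference radius about the
    reference centre of mass, as for Mr) are averaged over segments.

    With ``return_segment_displacements`` the raw per-segment projections and
    displacement vectors are returned too (used by the recombination check).
    """
    if grid_points % n_segments != 0:
        raise InvalidInputError(
            f"grid_points ({grid_points}) must be a multiple of n_segments ({n_segments}) "
            "to match the radial segmentation of the strain engine"
        )
    res = seq.resampled(grid_points)
    c0 = center_of_mass(res.frames[0])
    p0 = res.frames[0].points
    seg_p0 = p0.reshape(n_segments, -1, 2).mean(axis=1)
    m0 = np.linalg.norm(seg_p0 - c0[None, :], axis=1)
    if np.any(m0 <= 1e-9):
        raise InvalidInputError("zero reference segment radius")

    u, v = geom.mv_axis, geom.mv_perp
    n_frames = res.n_frames
    cmr = np.zeros(n_frames)
    pmr = np.zeros(n_frames)
    disp_all = np.zeros((n_frames, n_segments, 2))
    for i, frame in enumerate(res.frames):
        seg_pt = frame.points.reshape(n_segments, -1, 2).mean(axis=1)
        d = seg_pt - seg_p0
        disp_all[i] = d
        cmr[i] = float(np.mean(np.abs(d @ u) / m0))
        pmr[i] = float(np.mean(np.abs(d @ v) / m0))
    if return_segment_displacements:
        return cmr, pmr, disp_all @ u, disp_all @ v, disp_all
    return cmr, pmr


def decomposed_phasic(
    cmr: np.ndarray,
    pmr: np.ndarray,
    times: np.ndarray,
    phases: PhaseBoundaries,
) -> dict[str, float]:
    """Phase amplitudes of the decomposed curves, in percent.

    Same extraction rule as the other phasic indices: R at the reservoir
    peak time, A between A-onset and cycle end, C = R - A.
    """

    def amplitudes(series: np.ndarray) -> tuple[float, float, float]:
        r = _at(series, times, phases.t_peak)
        a = _at(series, times, phases.t_a_onset) - _at(series, times, phases.cycle_end)
        return 100 * r, 100 * (r - a), 100 * a

    cr, cc, ca = amplitudes(np.asarray(cmr, dtype=float))
    pr, pc, pa = amplitudes(np.asarray(pmr, dtype=float))
    return {"cmr_r": cr, "cmr_c": cc, "cmr_a": ca, "pmr_r": pr, "pmr_c": pc, "pmr_a": pa}


def attach_decomposition(indices: PhasicIndices, decomposed: dict[str, float]) -> PhasicIndices:
    """PhasicIndices with cmr/pmr fields filled from :func:`decomposed_phasic`."""
    from dataclasses import replace

    return replace(indices, **decomposed)
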