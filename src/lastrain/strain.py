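"""Phasic left-atrial strain and radial motion analysis.

From tracked endocardial contours this module computes

* longitudinal strain  Sl(t) = (Lt - L0) / L0  — fractional change of the
  contour length relative to the reference (trigger) frame;
* radial motion fraction  Mr(t) = (Mt - M0) / M0  — fractional change of
  per-segment radii measured toward the reference-frame centre of mass,
  averaged over segments;
* their temporal derivatives (longitudinal strain rate SRl and radial
  relative velocity Vr, in s^-1);
* the three atrial phases — reservoir (filling during ventricular systole),
  conduit (passive early-diastolic emptying) and atrial contraction (active
  late-diastolic emptying) — and the scalar indices of each phase.

The reference frame is frame 0 of the cine (the acquisition trigger, where
the LA is near its minimum volume), so both Sl and Mr rise to a positive
reservoir peak. The centre of mass used for radii is that of the reference
frame and is held fixed across the cycle: ventricular translation then shows
up as radial motion, which is what the mitral-valve decomposition
(:mod:`lastrain.decomposition`) subsequently separates out.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import InvalidInputError, PhaseDetectionError
from .geometry import (
    DEFAULT_GRID_POINTS,
    DEFAULT_N_SEGMENTS,
    ContourSequence,
    center_of_mass,
    contour_length,
    segment_radii,
)

#: Fraction of the cycle (from the end) within which atrial-contraction onset
#: is searched. Late diastole; no ECG P-wave timing exists in the data model.
A_ONSET_SEARCH_FRACTION = 0.4


@dataclass(frozen=True)
class StrainCurves:
    """Time series of Sl, Mr and their temporal derivatives.

    ``sl`` and ``mr`` are dimensionless fractions (rendered x100 as % in
    reports); ``srl`` and ``vr`` are their derivatives in s^-1.
    """

    times: np.ndarray
    sl: np.ndarray
    mr: np.ndarray
    srl: np.ndarray
    vr: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("sl", "mr", "srl", "vr"):
            if len(getattr(self, name)) != n:
                raise InvalidInputError(f"{name} length differs from times")


@dataclass(frozen=True)
class PhaseBoundaries:
    """Reservoir / conduit / contraction boundaries in ms.

    reservoir = [0, t_peak], conduit = [t_peak, t_a_onset],
    contraction = [t_a_onset, cycle_end].
    """

    t_peak: float
    t_a_onset: float
    cycle_end: float

    def __post_init__(self) -> None:
        if not (0.0 < self.t_peak < self.t_a_onset < self.cycle_end):
            raise InvalidInputError(
                f"phase boundaries must satisfy 0 < t_peak < t_a_onset < cycle_end, "
                f"got {self.t_peak}, {self.t_a_onset}, {self.cycle_end}"
            )


# Scalar index fields. Strain / motion-fraction entries are percent; rate
# entries are s^-1; ratio entries dimensionless (magnitude ratios).
_PCT_FIELDS = ("sl_r", "sl_c", "sl_a", "mr_r", "mr_c", "mr_a", "cmr_r", "cmr_c", "cmr_a", "pmr_r", "pmr_c", "pmr_a")
_RATE_FIELDS = ("srl_s", "srl_e", "srl_a", "vr_s", "vr_e", "vr_a")
_RATIO_FIELDS = ("sl_a_over_sl_r", "srl_e_over_a", "mr_a_over_mr_r", "vr_e_over_a")


@dataclass(frozen=True)
class PhasicIndices:
    """Per-phase scalar indices (Table-2-style readout for one subject/view).

    Longitudinal strain Sl and radial motion fraction Mr are reported per
    phase in percent, with additivity R = C + A exact by construction.
    Rate peaks: S' is the positive reservoir peak, E' and A' the negative
    conduit and contraction peaks; the E'/A' ratio is a ratio of magnitudes.
    cmr_*/pmr_* hold the MV-centric / MV-perpendicular decomposition when
    computed (0 otherwise).
    """

    sl_r: float = 0.0
    sl_c: float = 0.0
    sl_a: float = 0.0
    sl_a_over_sl_r: float = 0.0
    srl_s: float = 0.0
    srl_e: float = 0.0
    srl_a: float = 0.0
    srl_e_over_a: float = 0.0
    mr_r: float = 0.0
    mr_c: float = 0.0
    mr_a: float = 0.0
    mr_a_over_mr_r: float = 0.0
    vr_s: float = 0.0
    vr_e: float = 0.0
    vr_a: float = 0.0
    vr_e_over_a: float = 0.0
    cmr_r: float = 0.0
    cmr_c: float = 0.0
    cmr_a: float = 0.0
    pmr_r: float = 0.0
    pmr_c: float = 0.0
    pmr_a: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def longitudinal_strain_curve(seq: ContourSequence) -> np.ndarray:
    """Sl(t) = (Lt - L0)/L0 per frame (dimensionless; sl[0] == 0)."""
    lengths = np.array([contour_length(f) for f in seq.frames])
    l0 = lengths[0]
    if l0 <= 0:
        raise InvalidInputError("reference contour has zero length")
    return (lengths - l0) / l0


def radial_motion_curve(
    seq: ContourSequence,
    n_segments: int = DEFAULT_N_SEGMENTS,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> np.ndarray:
    """Mr(t): mean over segments of (Mt - M0)/M0 (dimensionless; mr[0] == 0).

    Radii are measured toward the centre of mass of the *reference* frame,
    held fixed for the whole cycle, so expansion during the reservoir phase
    is positive and rigid translation registers as radial motion.
    """
    c0 = center_of_mass(seq.frames[0])
    radii = np.stack([segment_radii(f, c0, n_segments, grid_points) for f in seq.frames])
    m0 = radii[0]
    if np.any(m0 <= 0):
        raise InvalidInputError("zero reference radius")
    per_segment = (radii - m0[None, :]) / m0[None, :]
    return per_segment.mean(axis=1)


def _moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the ends."""
    if window <= 1:
        return series
    half = window // 2
    out = np.empty_like(series, dtype=float)
    n = len(series)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = series[lo:hi].mean()
    return out


def rate_curve(series: np.ndarray, times: np.ndarray, smooth_window: int | None = None) -> np.ndarray:
    """Temporal derivative in s^-1 of a dimensionless series sampled at ``times`` (ms).

    Centered finite differences on interior points, one-sided at the ends;
    an optional moving average (``smooth_window`` points) is applied before
    differentiating to tame 20-phase cine noise.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(series) != len(times):
        raise InvalidInputError("series and times lengths differ")
    if len(series) < 3:
        raise InvalidInputError("need at least 3 samples to differentiate")
    if np.any(np.diff(times) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    if smooth_window:
        series = _moving_average(series, smooth_window)
    return np.gradient(series, times / 1000.0)


def detect_phases(
    sl: np.ndarray,
    times: np.ndarray,
    a_onset_override: float | None = None,
    search_fraction: float = A_ONSET_SEARCH_FRACTION,
) -> PhaseBoundaries:
    """Locate the reservoir peak and atrial-contraction onset from curve shape.

    The reservoir peak is the global maximum of Sl. A-onset is the
    mid-diastolic shoulder: the sample between the peak and the cycle end —
    constrained to the last ``search_fraction`` of the cycle — where the
    strain-rate magnitude is smallest (passive emptying has slowed; active
    contraction has not started). An explicit ``a_onset_override`` (ms, e.g.
    from ECG P-wave timing) bypasses the shoulder rule.
    """
    sl = np.asarray(sl, dtype=float)
    times = np.asarray(times, dtype=float)
    n = len(sl)
    i_peak = int(np.argmax(sl))
    if i_peak == 0 or i_peak == n - 1 or sl[i_peak] <= 0:
        raise PhaseDetectionError(
            f"no interior reservoir peak: argmax at frame {i_peak} with value {sl[i_peak]:.4g}"
        )
    t_peak = times[i_peak]
    cycle_end = times[-1]
    if a_onset_override is not None:
        return PhaseBoundaries(t_peak=t_peak, t_a_onset=float(a_onset_override), cycle_end=cycle_end)

    srl = rate_curve(sl, times)
    t_min = max(t_peak, cycle_end * (1.0 - search_fraction))
    candidates = [i for i in range(i_peak + 1, n - 1) if times[i] >= t_min]
    if not candidates:
        raise PhaseDetectionError("no candidate frames for atrial-contraction onset in the search window")
    # smallest |rate|; ties (a genuinely linear/flat conduit tail) resolve to
    # the latest tied frame, where passive emptying actually ends
    mags = np.abs(srl[candidates])
    m = mags.min()
    i_a = max(i for i, mag in zip(candidates, mags) if mag <= m * (1.0 + 1e-6) + 1e-12)
    return PhaseBoundaries(t_peak=t_peak, t_a_onset=times[i_a], cycle_end=cycle_end)


def _at(series: np.ndarray, times: np.ndarray, t: float) -> float:
    """Series value at the frame closest to time t."""
    return float(series[int(np.argmin(np.abs(times - t)))])


def _window(times: np.ndarray, t0: float, t1: float) -> np.ndarray:
    mask = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
    if not mask.any():
        raise PhaseDetectionError(f"empty phase window [{t0}, {t1}] ms")
    return mask


def _mag_ratio(num: float, den: float) -> float:
    return abs(num) / abs(den) if den != 0 else float("nan")


def phasic_indices(curves: StrainCurves, phases: PhaseBoundaries) -> PhasicIndices:
    """Extract all per-phase scalar indices from one set of curves.

    Reservoir amplitude is the curve value at the peak; contraction amplitude
    is the value at A-onset minus the end-of-cycle value; conduit amplitude
    is their difference, so R = C + A holds exactly. Rate indices are the
    signed extrema of the rate curve inside each phase window.
    """
    t, sl, mr, srl, vr = curves.times, curves.sl, curves.mr, curves.srl, curves.vr
    if not (t[0] <= phases.t_peak <= t[-1] and phases.t_a_onset <= t[-1]):
        raise InvalidInputError("phase boundaries outside the sampled time range")

    def amplitudes(series: np.ndarray) -> tuple[float, float, float]:
        r = _at(series, t, phases.t_peak)
        a = _at(series, t, phases.t_a_onset) - _at(series, t, phases.cycle_end)
        return r, r - a, a  # (R, C, A); additivity exact

    sl_r, sl_c, sl_a = amplitudes(sl)
    mr_r, mr_c, mr_a = amplitudes(mr)

    w_res = _window(t, t[0], phases.t_peak)
    w_con = _window(t, phases.t_peak, phases.t_a_onset)
    w_a = _window(t, phases.t_a_onset, phases.cycle_end)

    srl_s, srl_e, srl_a_ = float(srl[w_res].max()), float(srl[w_con].min()), float(srl[w_a].min())
    vr_s, vr_e, vr_a_ = float(vr[w_res].max()), float(vr[w_con].min()), float(vr[w_a].min())

    return PhasicIndices(
        sl_r=100 * sl_r,
        sl_c=100 * sl_c,
        sl_a=100 * sl_a,
        sl_a_over_sl_r=sl_a / sl_r if sl_r != 0 else float("nan"),
        srl_s=srl_s,
        srl_e=srl_e,
        srl_a=srl_a_,
        srl_e_over_a=_mag_ratio(srl_e, srl_a_),
        mr_r=100 * mr_r,
        mr_c=100 * mr_c,
        mr_a=100 * mr_a,
        mr_a_over_mr_r=mr_a / mr_r if mr_r != 0 else float("nan"),
        vr_s=vr_s,
        vr_e=vr_e,
        vr_a=vr_a_,
        vr_e_over_a=_mag_ratio(vr_e, vr_a_),
    )


def global_average(per_view: list[PhasicIndices]) -> PhasicIndices:
    """Field-wise mean over 1-3 long-axis views.

    Amplitude and rate fields average arithmetically; ratio fields are
    recomputed from the averaged numerators and denominators so that the
    global ratio remains a ratio of global quantities.
    """
    if not per_view:
        raise InvalidInputError("global_average needs at least one view")
    mean = {
        name: float(np.mean([getattr(p, name) for p in per_view]))
        for name in (*_PCT_FIELDS, *_RATE_FIELDS)
    }
    mean["sl_a_over_sl_r"] = mean["sl_a"] / mean["sl_r"] if mean["sl_r"] != 0 else float("nan")
    mean["mr_a_over_mr_r"] = mean["mr_a"] / mean["mr_r"] if mean["mr_r"] != 0 else float("nan")
    mean["srl_e_over_a"] = _mag_ratio(mean["srl_e"], mean["srl_a"])
    mean["vr_e_over_a"] = _mag_ratio(mean["vr_e"], mean["vr_a"])
    return PhasicIndices(**mean)


def compute_strain_curves(
    seq: ContourSequence,
    n_segments: int = DEFAULT_N_SEGMENTS,
    smooth_window: int | None = 3,
) -> StrainCurves:
    """Full curve set for one view: Sl, Mr and their rate curves."""
    sl = longitudinal_strain_curve(seq)
    mr = radial_motion_curve(seq, n_segments=n_segments)
    return StrainCurves(
        times=seq.times,
        sl=sl,
        mr=mr,
        srl=rate_curve(sl, seq.times, smooth_window=smooth_window),
        vr=rate_curve(mr, seq.times, smooth_window=smooth_window),
    )
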