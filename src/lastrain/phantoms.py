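"""Synthetic phantoms with known ground truth.

Three generators cover every input the analysis needs:

* :func:`make_la_phantom` — dynamic LA endocardial contour sequences for the
  three long-axis views. The wall is an open elliptical arc
  (annulus-to-annulus); its motion is a uniform scaling about the
  reference-frame centre of mass following a piecewise-cosine strain curve,
  plus an optional rigid translation along/across the MV axis emulating
  ventricular drag. Cosine segments make phase boundaries and phasic
  amplitudes exact by construction while keeping derivatives continuous.
* :func:`make_dixon_phantom` — concentric-sphere Dixon fat/water volumes:
  blood pool, myocardial shell with a set fat fraction, epicardial fat shell
  of known (voxel-counted) volume, plus the cardiac mask and a septal ROI.
* :func:`make_cohort` — two-group cohort tables drawn from per-variable
  normal distributions; the default effect table carries the control/ObT2D
  group means and SDs of the study this pipeline models.

All ground truths are computed by construction (closed-form perimeters,
voxel counts), never by the analysis code under test. Same seed, same
output, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .geometry import VIEWS, Contour, ContourSequence

# Per-view shape/amplitude modifiers: rotation (deg), in-plane squeeze of the
# short ellipse axis, and a strain-amplitude multiplier. The multipliers
# average to exactly 1 so the cross-view global mean equals the set target.
_VIEW_ROTATION_DEG = {"2-chamber": -12.0, "4-chamber": 0.0, "3-chamber": 12.0}
_VIEW_SQUEEZE = {"2-chamber": 0.95, "4-chamber": 1.0, "3-chamber": 1.05}
_VIEW_AMPLITUDE = {"2-chamber": 0.98, "4-chamber": 1.0, "3-chamber": 1.02}


@dataclass(frozen=True)
class LAMotionParams:
    """Parameters of the dynamic LA contour phantom.

    Strain targets are in percent (reservoir peak ``sl_r_true`` and atrial
    contraction amplitude ``sl_a_true``); phase times are cycle fractions;
    translation amplitudes are mm along / across the MV axis; ``noise_sd``
    is per-coordinate Gaussian jitter in mm.
    """

    base_radius_mm: float = 30.0
    eccentricity: float = 0.15
    sl_r_true: float = 33.2
    sl_a_true: float = 16.7
    t_peak_frac: float = 0.4
    t_a_onset_frac: float = 0.75
    translation_along_mm: float = 0.0
    translation_across_mm: float = 0.0
    n_frames: int = 20
    cycle_ms: float = 1000.0
    n_points: int = 120
    arc_halfgap_deg: float = 20.0
    noise_sd_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.t_peak_frac < self.t_a_onset_frac < 1.0):
            raise InvalidInputError("need 0 < t_peak_frac < t_a_onset_frac < 1")
        if self.sl_a_true > self.sl_r_true:
            raise InvalidInputError(
                "infeasible strain targets: contraction amplitude exceeds reservoir peak "
                "(negative conduit)"
            )
        if self.sl_r_true < 0 or self.n_frames < 10 or self.base_radius_mm <= 0:
            raise InvalidInputError("invalid phantom parameters")


def strain_waveform(t_frac: np.ndarray, r: float, a: float, tp: float, ta: float) -> np.ndarray:
    """Piecewise-cosine strain curve (dimensionless) on cycle fractions.

    Rises 0 -> r on [0, tp], falls r -> a on [tp, ta], falls a -> 0 on
    [ta, 1]; zero slope at every breakpoint, so the phase boundaries are the
    exact stationary points of the derivative magnitude.
    """
    t = np.asarray(t_frac, dtype=float)
    g = np.empty_like(t)
    rise = t <= tp
    conduit = (t > tp) & (t <= ta)
    booster = t > ta
    g[rise] = r * (1.0 - np.cos(np.pi * t[rise] / tp)) / 2.0
    g[conduit] = a + (r - a) * (1.0 + np.cos(np.pi * (t[conduit] - tp) / (ta - tp))) / 2.0
    g[booster] = a * (1.0 + np.cos(np.pi * (t[booster] - ta) / (1.0 - ta))) / 2.0
    return g


def _arc_centroid(points: np.ndarray) -> np.ndarray:
    # independent arc-length-weighted centroid with chord closure
    chain = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    mid = 0.5 * (chain[:-1] + chain[1:])
    return (mid * seg[:, None]).sum(axis=0) / seg.sum()


def _reference_arc(params: LAMotionParams, view: str) -> np.ndarray:
    """Open elliptical arc, annulus insertion to annulus insertion."""
    gap = np.deg2rad(params.arc_halfgap_deg)
    theta = np.linspace(-np.pi / 2 + gap, 3 * np.pi / 2 - gap, params.n_points)
    a = params.base_radius_mm * (1.0 + params.eccentricity)
    b = params.base_radius_mm * (1.0 - params.eccentricity) * _VIEW_SQUEEZE[view]
    pts = np.column_stack([a * np.cos(theta), -b * np.sin(theta)])
    # endpoints flank theta = -pi/2, i.e. the MV plane sits at image-bottom
    # (y positive-down convention); rotate per view
    phi = np.deg2rad(_VIEW_ROTATION_DEG[view])
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    return pts @ rot.T


def make_la_phantom(params: LAMotionParams) -> tuple[dict[str, ContourSequence], dict[str, float]]:
    """Generate the three-view contour phantom and its ground-truth record.

    Frame times span the full cycle inclusive of both ends (frame 0 and the
    last frame are the zero-strain reference state). With zero translation
    and zero noise both Sl(t) and Mr(t) equal the set waveform exactly.
    """
    rng = np.random.default_rng(params.seed)
    t_frac = np.linspace(0.0, 1.0, params.n_frames)
    times = t_frac * params.cycle_ms
    r_frac, a_frac = params.sl_r_true / 100.0, params.sl_a_true / 100.0

    sequences: dict[str, ContourSequence] = {}
    for view in VIEWS:
        p0 = _reference_arc(params, view)
        c0 = _arc_centroid(p0)
        mv_center0 = 0.5 * (p0[0] + p0[-1])
        axis = mv_center0 - c0
        u = axis / np.linalg.norm(axis)
        v = np.array([-u[1], u[0]])
        g = strain_waveform(t_frac, r_frac, a_frac, params.t_peak_frac, params.t_a_onset_frac)
        g = g * _VIEW_AMPLITUDE[view]
        tau = g / (r_frac * _VIEW_AMPLITUDE[view]) if r_frac > 0 else np.zeros_like(g)
        shift = np.outer(tau, params.translation_along_mm * u + params.translation_across_mm * v)

        frames, mv_pts = [], []
        for i in range(params.n_frames):
            pts = c0 + (1.0 + g[i]) * (p0 - c0) + shift[i]
            if params.noise_sd_mm > 0 and i > 0:
                pts = pts + rng.normal(0.0, params.noise_sd_mm, size=pts.shape)
            frames.append(Contour(points=pts, closed=False))
            mv_pts.append([pts[0], pts[-1]])
        sequences[view] = ContourSequence(
            frames=tuple(frames), times=times, view=view, mv_points=np.array(mv_pts)
        )

    sl_c_true = params.sl_r_true - params.sl_a_true
    tp_s = params.t_peak_frac * params.cycle_ms / 1000.0
    ta_s = params.t_a_onset_frac * params.cycle_ms / 1000.0
    t_end_s = params.cycle_ms / 1000.0
    truth = {
        "sl_r": params.sl_r_true,
        "sl_c": sl_c_true,
        "sl_a": params.sl_a_true,
        "sl_a_over_sl_r": params.sl_a_true / params.sl_r_true if params.sl_r_true else float("nan"),
        # with zero translation the motion is pure scaling about the centre,
        # so the radial indices coincide with the longitudinal ones
        "mr_r": params.sl_r_true,
        "mr_c": sl_c_true,
        "mr_a": params.sl_a_true,
        "t_peak_ms": params.t_peak_frac * params.cycle_ms,
        "t_a_onset_ms": params.t_a_onset_frac * params.cycle_ms,
        # analytic peak derivatives of the cosine segments (s^-1)
        "srl_s": r_frac * np.pi / (2.0 * tp_s),
        "srl_e": -(r_frac - a_frac) * np.pi / (2.0 * (ta_s - tp_s)),
        "srl_a": -a_frac * np.pi / (2.0 * (t_end_s - ta_s)),
        "translation_along_mm": params.translation_along_mm,
        "translation_across_mm": params.translation_across_mm,
    }
    return sequences, truth


def control_decomposition_params(**overrides) -> LAMotionParams:
    """Control-cohort-scale LA phantom for the MV decomposition.

    Strain targets are the control-group means (Sl_R 33.2%, Sl_A 16.7%);
    the translation amplitudes were calibrated once so the decomposition
    readouts sit at the control-cohort scale (cMr_A ~ 20.3%, pMr_R ~ 53.3%):
    a ventricle-dragged atrium translating ~13 mm along and ~16 mm across
    the MV axis over the cycle.
    """
    defaults = dict(
        sl_r_true=33.2,
        sl_a_true=16.7,
        translation_along_mm=13.25,
        translation_across_mm=15.95,
    )
    defaults.update(overrides)
    return LAMotionParams(**defaults)


@dataclass(frozen=True)
class DixonPhantomParams:
    """Concentric-sphere Dixon phantom parameters.

    Volumes are targets in mL (realised volumes are voxel-counted and
    reported in the truth record). Intensities are arbitrary units; noise is
    Gaussian per channel, clipped at zero. ``noise_sd = fat_intensity / SNR``.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    mask_volume_ml: float = 840.0
    fat_volume_ml: float = 176.4
    myo_thickness_mm: float = 10.0
    myo_ff_pct: float = 6.0
    fat_intensity: float = 900.0
    water_intensity: float = 1000.0
    blood_fat_intensity: float = 50.0
    fat_shell_water_intensity: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.myo_ff_pct <= 100.0):
            raise InvalidInputError("myocardial fat fraction must be within [0, 100]%")
        if self.fat_volume_ml < 0 or self.fat_volume_ml >= self.mask_volume_ml:
            raise InvalidInputError("fat volume must be non-negative and below the mask volume")
        extent = min(n * v for n, v in zip(self.grid_shape, self.voxel_size_mm))
        if 2.0 * _sphere_radius_mm(self.mask_volume_ml) > extent:
            raise InvalidInputError("mask sphere does not fit inside the grid")


def _sphere_radius_mm(volume_ml: float) -> float:
    return (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def make_dixon_phantom(params: DixonPhantomParams):
    """Build the Dixon phantom; returns (DixonStudy, truth record).

    Geometry (radii solved from the target volumes): blood pool r < r1,
    myocardial shell r1..r2 with the set fat fraction, epicardial fat shell
    r2..R; the cardiac mask is the full sphere r <= R. The truth record
    holds the voxel-counted volumes, which is what a perfect segmentation
    of this digital phantom would measure.
    """
    from .fat import DixonStudy

    nz, ny, nx = params.grid_shape
    vz, vy, vx = params.voxel_size_mm
    zc, yc, xc = ((n - 1) / 2.0 for n in params.grid_shape)
    z, y, x = np.meshgrid(
        (np.arange(nz) - zc) * vz,
        (np.arange(ny) - yc) * vy,
        (np.arange(nx) - xc) * vx,
        indexing="ij",
    )
    r = np.sqrt(x**2 + y**2 + z**2)

    r_mask = _sphere_radius_mm(params.mask_volume_ml)
    r2 = _sphere_radius_mm(params.mask_volume_ml - params.fat_volume_ml)
    r1 = max(r2 - params.myo_thickness_mm, 0.1 * r2)

    mask = r <= r_mask
    fat_shell = (r > r2) & mask
    myo_shell = (r > r1) & (r <= r2)
    blood = r <= r1

    ff = params.myo_ff_pct / 100.0
    total = params.water_intensity  # F + W inside tissue
    fat_img = np.zeros(params.grid_shape)
    water_img = np.zeros(params.grid_shape)
    fat_img[blood] = params.blood_fat_intensity
    water_img[blood] = params.water_intensity
    fat_img[myo_shell] = ff * total
    water_img[myo_shell] = (1.0 - ff) * total
    fat_img[fat_shell] = params.fat_intensity
    water_img[fat_shell] = params.fat_shell_water_intensity

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        fat_img = np.clip(fat_img + rng.normal(0.0, params.noise_sd, fat_img.shape), 0.0, None)
        water_img = np.clip(water_img + rng.normal(0.0, params.noise_sd, water_img.shape), 0.0, None)

    # septal ROI: a wedge of the myocardial shell on the central slice
    roi_slice = nz // 2
    sl_myo = myo_shell[roi_slice]
    wedge = (np.abs(y[roi_slice]) < max(0.25 * r2, 3.0 * vy)) & (x[roi_slice] > 0)
    roi = sl_myo & wedge
    if not roi.any():  # extremely thin shells: fall back to the whole in-slice shell
        roi = sl_myo

    voxel_ml = (vx * vy * vz) / 1000.0
    study = DixonStudy(
        fat=fat_img,
        water=water_img,
        voxel_size_mm=params.voxel_size_mm,
        cardiac_mask=mask,
        septal_roi=roi,
        roi_slice=roi_slice,
    )
    truth = {
        "efv_ml": float(fat_shell.sum()) * voxel_ml,
        "mask_ml": float(mask.sum()) * voxel_ml,
        "ef_fraction_pct": 100.0 * fat_shell.sum() / mask.sum(),
        "intramyo_ff_pct": params.myo_ff_pct,
        "n_roi_voxels": int(roi.sum()),
    }
    return study, truth


# Group means and SDs (control, ObT2D) of the modelled study's published
# cohort tables; used as the default effect table for simulated cohorts.
DEFAULT_EFFECT_TABLE: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "sl_r": ((33.2, 6.8), (29.4, 8.4)),
    "sl_c": ((16.5, 4.8), (13.1, 5.0)),
    "sl_a": ((16.7, 3.9), (16.8, 4.8)),
    "sl_a_over_sl_r": ((0.5, 0.1), (0.6, 0.1)),
    "srl_s": ((1.4, 0.3), (1.4, 0.4)),
    "srl_e": ((-1.5, 0.4), (-1.2, 0.6)),
    "srl_a": ((-1.4, 0.4), (-1.5, 0.5)),
    "srl_e_over_a": ((1.2, 0.5), (0.9, 0.3)),
    "mr_r": ((35.1, 6.7), (31.5, 9.1)),
    "mr_c": ((17.2, 4.7), (13.6, 5.9)),
    "mr_a": ((17.9, 4.3), (18.2, 4.3)),
    "mr_a_over_mr_r": ((0.5, 0.1), (0.6, 0.1)),
    "vr_s": ((1.4, 0.3), (1.5, 0.6)),
    "vr_e": ((-1.6, 0.5), (-1.3, 0.6)),
    "vr_a": ((-1.5, 0.5), (-1.8, 0.6)),
    "vr_e_over_a": ((1.2, 0.5), (0.7, 0.2)),
    "cmr_r": ((34.3, 9.6), (37.2, 10.6)),
    "cmr_c": ((14.0, 5.7), (11.3, 5.7)),
    "cmr_a": ((20.3, 5.6), (26.0, 6.3)),
    "pmr_r": ((53.3, 17.8), (42.5, 12.6)),
    "pmr_c": ((21.0, 15.2), (14.0, 9.5)),
    "pmr_a": ((32.3, 10.7), (28.6, 10.7)),
    "efv_abs": ((176.4, 68.6), (273.8, 64.0)),
    "efv_indexed": ((89.7, 25.2), (123.6, 23.4)),
    "ef_fraction": ((21.0, 4.0), (28.4, 5.5)),
    "intramyo_ff": ((7.9, 3.7), (6.0, 1.5)),
    "bsa": ((1.9, 0.2), (2.2, 0.2)),
    "bmi": ((24.8, 2.6), (39.7, 5.8)),
}


def make_cohort(
    n_control: int,
    n_case: int,
    effect_table: dict[str, tuple[tuple[float, float], tuple[float, float]]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a tidy two-group cohort table.

    One row per (subject, variable); values drawn from per-group normal
    distributions given by ``effect_table`` (default: the published group
    means/SDs). Columns: subject_id, group, variable, value.
    """
    if n_control < 1 or n_case < 1:
        raise InvalidInputError("group sizes must be positive")
    table = effect_table if effect_table is not None else DEFAULT_EFFECT_TABLE
    rng = np.random.default_rng(seed)
    rows = []
    groups = [("control", n_control), ("ObT2D", n_case)]
    for gi, (group, n) in enumerate(groups):
        for s in range(n):
            sid = f"{'C' if group == 'control' else 'P'}{s + 1:03d}"
            for var, group_params in table.items():
                mean, sd = group_params[gi]
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "variable": var,
                        "value": rng.normal(mean, sd),
                    }
                )
    return pd.DataFrame(rows)
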