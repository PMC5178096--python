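"""File formats: contour CSV + JSON sidecar, NIfTI volumes, cohort CSV.

Contour dialect
---------------
``<stem>.csv`` with columns ``frame_index, point_index, x_mm, y_mm`` and a
JSON sidecar ``<stem>.json`` holding ``{"view": ..., "times_ms": [...],
"mv_points": [[[x,y],[x,y]], ...]}``. The reader validates the sequence
invariants and reports offending CSV line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fat import DixonStudy
from .geometry import Contour, ContourSequence

CONTOUR_COLUMNS = ["frame_index", "point_index", "x_mm", "y_mm"]


def write_contour_sequence(seq: ContourSequence, stem: Path | str) -> tuple[Path, Path]:
    """Write one view's contour sequence as CSV + JSON sidecar."""
    stem = Path(stem)
    rows = []
    for fi, frame in enumerate(seq.frames):
        for pi, (x, y) in enumerate(frame.points):
            rows.append((fi, pi, x, y))
    df = pd.DataFrame(rows, columns=CONTOUR_COLUMNS)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    df.to_csv(csv_path, index=False)
    sidecar = {
        "view": seq.view,
        "times_ms": seq.times.tolist(),
        "mv_points": seq.mv_points.tolist() if seq.mv_points is not None else None,
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_contour_sequence(stem: Path | str) -> ContourSequence:
    """Read a contour CSV + sidecar pair back into a ContourSequence."""
    stem = Path(stem)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    if not csv_path.exists() or not json_path.exists():
        raise InvalidInputError(f"missing contour file pair {csv_path} / {json_path}")
    df = pd.read_csv(csv_path)
    missing = set(CONTOUR_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{csv_path}: missing columns {sorted(missing)}")
    bad = df.index[~np.isfinite(df[["x_mm", "y_mm"]]).all(axis=1)]
    if len(bad):
        raise InvalidInputError(f"{csv_path}: non-finite coordinates at line {bad[0] + 2}")
    sidecar = json.loads(json_path.read_text())
    frames = []
    for fi, sub in df.groupby("frame_index", sort=True):
        sub = sub.sort_values("point_index")
        frames.append(Contour(points=sub[["x_mm", "y_mm"]].to_numpy(), closed=False))
    mv = sidecar.get("mv_points")
    return ContourSequence(
        frames=tuple(frames),
        times=np.asarray(sidecar["times_ms"], dtype=float),
        view=sidecar["view"],
        mv_points=np.asarray(mv, dtype=float) if mv is not None else None,
    )


def write_dixon_study(study: DixonStudy, outdir: Path | str) -> dict[str, Path]:
    """Write a Dixon study as NIfTI volumes (fat, water, mask, ROI)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*study.voxel_size_mm, 1.0])
    paths = {}
    for name, arr in (("fat", study.fat), ("water", study.water)):
        p = outdir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), p)
        paths[name] = p
    p = outdir / "mask.nii.gz"
    nib.save(nib.Nifti1Image(study.cardiac_mask.astype(np.uint8), affine), p)
    paths["mask"] = p
    if study.septal_roi is not None:
        roi3d = np.zeros(study.fat.shape, dtype=np.uint8)
        roi3d[study.roi_slice] = study.septal_roi
        p = outdir / "roi.nii.gz"
        nib.save(nib.Nifti1Image(roi3d, affine), p)
        paths["roi"] = p
    return paths


def read_dixon_study(
    fat_path: Path | str,
    water_path: Path | str,
    mask_path: Path | str,
    roi_path: Path | str | None = None,
) -> DixonStudy:
    """Read fat/water/mask (and optional 3D ROI) NIfTI volumes."""
    fat_img = nib.load(str(fat_path))
    fat = np.asarray(fat_img.dataobj, dtype=float)
    water = np.asarray(nib.load(str(water_path)).dataobj, dtype=float)
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    voxel = tuple(float(z) for z in fat_img.header.get_zooms()[:3])
    roi2d, roi_slice = None, None
    if roi_path is not None:
        roi3d = np.asarray(nib.load(str(roi_path)).dataobj) > 0
        hit = np.flatnonzero(roi3d.reshape(roi3d.shape[0], -1).any(axis=1))
        if len(hit) != 1:
            raise InvalidInputError("septal ROI must live on exactly one slice")
        roi_slice = int(hit[0])
        roi2d = roi3d[roi_slice]
    return DixonStudy(
        fat=fat, water=water, voxel_size_mm=voxel, cardiac_mask=mask,
        septal_roi=roi2d, roi_slice=roi_slice,
    )


def write_curves_tidy(curves_by_view: dict, path: Path | str) -> Path:
    """Write strain/motion curves in tidy long format.

    Columns: time_ms, quantity (sl | mr | srl | vr | cmr | pmr), view, value.
    """
    rows = []
    for view, qdict in curves_by_view.items():
        times = qdict["times"]
        for quantity, series in qdict.items():
            if quantity == "times":
                continue
            for t, val in zip(times, series):
                rows.append({"time_ms": t, "quantity": quantity, "view": view, "value": val})
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_cohort(path: Path | str) -> pd.DataFrame:
    """Read a tidy cohort CSV (subject_id, group, variable, value)."""
    df = pd.read_csv(path)
    required = {"subject_id", "group", "variable", "value"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: cohort table missing columns {sorted(missing)}")
    return df
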