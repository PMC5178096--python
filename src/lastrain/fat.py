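"""2-point-Dixon cardiac fat quantification.

Two readouts:

* **intra-myocardial fat fraction** — the mean voxelwise Dixon fat fraction
  F/(F+W) over a hand-drawn septal ROI on a designated 4-chamber-equivalent
  slice, in percent;
* **epicardial fat volume / fraction** — K-means clustering (default k=2)
  of fat-image intensities inside a whole-heart cardiac mask; the cluster
  with the highest mean fat intensity is the adipose class. Absolute volume
  is adipose voxel count x voxel volume; the fraction divides by the whole
  mask volume. BSA indexing normalises the absolute volume by body size.

No T2* or bias-field correction is applied: inputs are assumed to be
reconstructed fat/water magnitude volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import ClusteringDegenerateError, InvalidInputError

DEFAULT_K = 2


@dataclass(frozen=True)
class DixonStudy:
    """Fat/water volumes plus the masks the fat measurements need.

    ``cardiac_mask`` covers the whole heart including the epicardial
    envelope; ``septal_roi`` is a 2D boolean region on slice ``roi_slice``
    (axis-0 index) covering the myocardial septum.
    """

    fat: np.ndarray
    water: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    cardiac_mask: np.ndarray
    septal_roi: np.ndarray | None = None
    roi_slice: int | None = None

    def __post_init__(self) -> None:
        fat = np.asarray(self.fat, dtype=float)
        water = np.asarray(self.water, dtype=float)
        mask = np.asarray(self.cardiac_mask, dtype=bool)
        if fat.shape != water.shape or fat.shape != mask.shape:
            raise InvalidInputError("fat, water and cardiac_mask shapes must match")
        if np.any(fat < 0) or np.any(water < 0):
            raise InvalidInputError("Dixon intensities must be non-negative")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidInputError("voxel size must be positive")
        object.__setattr__(self, "fat", fat)
        object.__setattr__(self, "water", water)
        object.__setattr__(self, "cardiac_mask", mask)
        if self.septal_roi is not None:
            roi = np.asarray(self.septal_roi, dtype=bool)
            if self.roi_slice is None or not (0 <= self.roi_slice < fat.shape[0]):
                raise InvalidInputError("septal_roi requires a valid roi_slice index")
            if roi.shape != fat.shape[1:]:
                raise InvalidInputError("septal_roi must match the in-plane volume shape")
            object.__setattr__(self, "septal_roi", roi)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    @property
    def mask_volume_ml(self) -> float:
        return float(self.cardiac_mask.sum()) * self.voxel_volume_ml


@dataclass(frozen=True)
class FatMeasures:
    """Assembled fat readouts for one subject."""

    intramyo_ff_pct: float
    efv_abs_ml: float
    efv_indexed_ml_m2: float
    ef_fraction_pct: float
    n_roi_voxels: int = 0
    n_roi_excluded: int = 0


def intramyocardial_fat_fraction(study: DixonStudy) -> tuple[float, dict[str, int]]:
    """Septal-ROI Dixon fat fraction: mean of F/(F+W) over ROI voxels, x100.

    Voxels with F+W == 0 carry no Dixon signal; they are excluded from the
    mean and counted in the returned QC dict.
    """
    if study.septal_roi is None or not study.septal_roi.any():
        raise InvalidInputError("empty or missing septal ROI")
    f = study.fat[study.roi_slice][study.septal_roi]
    w = study.water[study.roi_slice][study.septal_roi]
    total = f + w
    valid = total > 0
    qc = {"n_voxels": int(valid.size), "n_excluded": int((~valid).sum())}
    if not valid.any():
        raise InvalidInputError("all ROI voxels have zero Dixon signal")
    ff = float(np.mean(f[valid] / total[valid]) * 100.0)
    return ff, qc


def epicardial_fat_kmeans(study: DixonStudy, k: int = DEFAULT_K, seed: int = 0) -> dict[str, float]:
    """Epicardial fat volume and fraction by K-means on fat intensities.

    Clusters the fat-image intensities of the voxels inside the cardiac mask
    (k-means++ initialisation, seeded, hence deterministic); the cluster with
    the highest centroid is adipose. Returns ``efv_abs`` (mL) and
    ``ef_fraction`` (% of the whole-heart mask volume).
    """
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    if not study.cardiac_mask.any():
        raise InvalidInputError("empty cardiac mask")
    values = study.fat[study.cardiac_mask].reshape(-1, 1)
    if np.unique(values).size < k:
        raise ClusteringDegenerateError(
            f"only {np.unique(values).size} distinct intensities in mask; cannot form {k} clusters"
        )
    km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=300, tol=1e-6)
    labels = km.fit_predict(values)
    adipose = int(np.argmax(km.cluster_centers_[:, 0]))
    n_fat = int((labels == adipose).sum())
    efv_abs = n_fat * study.voxel_volume_ml
    return {
        "efv_abs": efv_abs,
        "ef_fraction": 100.0 * efv_abs / study.mask_volume_ml,
    }


def fat_measures(study: DixonStudy, bsa: float, k: int = DEFAULT_K, seed: int = 0) -> FatMeasures:
    """All fat readouts for one subject: ROI fat fraction, EFV, indexed EFV."""
    if bsa <= 0:
        raise InvalidInputError("BSA must be positive")
    ff, qc = intramyocardial_fat_fraction(study)
    ep = epicardial_fat_kmeans(study, k=k, seed=seed)
    return FatMeasures(
        intramyo_ff_pct=ff,
        efv_abs_ml=ep["efv_abs"],
        efv_indexed_ml_m2=ep["efv_abs"] / bsa,
        ef_fraction_pct=ep["ef_fraction"],
        n_roi_voxels=qc["n_voxels"],
        n_roi_excluded=qc["n_excluded"],
    )
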