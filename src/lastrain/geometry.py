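"""Contour geometry primitives.

Everything downstream (strain, radial motion fraction, the MV decomposition)
is built from four operations on planar endocardial contours: uniform
arc-length resampling, total length, the arc-length-weighted centroid, and
per-segment radii about a centre.

Conventions
-----------
Coordinates are millimetres in the image plane (y increases downward, as in
image rasters); nothing here depends on that orientation. LA contours are
open polylines running from one mitral-annulus insertion to the other — the
valve plane is not part of the atrial wall — and are closed by the chord
between their endpoints for centroid purposes only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidGeometryError, InvalidInputError

VIEWS = ("2-chamber", "4-chamber", "3-chamber")

#: Number of points contours are resampled to before radii are pooled.
DEFAULT_GRID_POINTS = 120
#: Number of contiguous radial segments the radii are pooled into.
DEFAULT_N_SEGMENTS = 12


@dataclass(frozen=True)
class Contour:
    """Ordered 2D trace of the LA endocardium.

    Parameters
    ----------
    points
        (N, 2) array of positions in mm, ordered along the wall.
    closed
        Whether the endpoints are joined by a real wall segment. LA contours
        are open (annulus-to-annulus); phantom test shapes may be closed.
    """

    points: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise InvalidGeometryError(f"contour needs an (N>=2, 2) point array, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise InvalidGeometryError("contour coordinates must be finite")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise InvalidGeometryError("consecutive contour points coincide")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def validate_strict(self) -> None:
        """Full input-data invariant: at least 8 points (constructor allows 2
        so that small analytic shapes can exercise the primitives)."""
        if self.n_points < 8:
            raise InvalidGeometryError(f"contour has {self.n_points} points; at least 8 required")


@dataclass(frozen=True)
class ContourSequence:
    """Per-frame LA contours for one long-axis cine view.

    ``times`` are frame times in ms, strictly increasing with ``times[0] == 0``
    (the reference phase, the cine trigger frame). ``mv_points`` holds the two
    mitral-annulus landmark positions per frame, shape (n_frames, 2, 2).
    """

    frames: tuple[Contour, ...]
    times: np.ndarray
    view: str = "4-chamber"
    mv_points: np.ndarray | None = None

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        times = np.asarray(self.times, dtype=float)
        if len(frames) != times.shape[0]:
            raise InvalidInputError("one frame time per contour frame required")
        if times.shape[0] < 10:
            raise InvalidInputError(
                f"insufficient temporal resolution: {times.shape[0]} frames (need >= 10)"
            )
        if times[0] != 0.0:
            raise InvalidInputError("times[0] must be 0 (reference phase)")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("frame times must be strictly increasing")
        if self.view not in VIEWS:
            raise InvalidInputError(f"view must be one of {VIEWS}, got {self.view!r}")
        for f in frames:
            f.validate_strict()
        if self.mv_points is not None:
            mv = np.asarray(self.mv_points, dtype=float)
            if mv.shape != (len(frames), 2, 2):
                raise InvalidInputError(f"mv_points must have shape (n_frames, 2, 2), got {mv.shape}")
            object.__setattr__(self, "mv_points", mv)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def resampled(self, n_points: int = DEFAULT_GRID_POINTS) -> "ContourSequence":
        """Return the sequence with every frame resampled to ``n_points``."""
        return ContourSequence(
            frames=tuple(resample_contour(f, n_points) for f in self.frames),
            times=self.times,
            view=self.view,
            mv_points=self.mv_points,
        )


def _vertex_chain(contour: Contour) -> np.ndarray:
    """Vertices of the polyline actually traversed (closing edge appended if closed)."""
    pts = contour.points
    if contour.closed:
        return np.vstack([pts, pts[:1]])
    return pts


def contour_length(contour: Contour) -> float:
    """Total Euclidean length of the contour polyline (mm).

    For closed contours the closing segment between last and first point is
    included; open contours are the plain polyline length.
    """
    chain = _vertex_chain(contour)
    return float(np.sum(np.linalg.norm(np.diff(chain, axis=0), axis=1)))


def resample_contour(contour: Contour, n_points: int) -> Contour:
    """Resample to ``n_points`` at uniform arc-length spacing.

    Points lie exactly on the piecewise-linear input curve; for open contours
    both endpoints are preserved, for closed contours the first point is
    preserved and spacing is uniform around the loop.
    """
    if n_points < 8:
        raise InvalidInputError(f"n_points must be >= 8, got {n_points}")
    chain = _vertex_chain(contour)
    seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0.0:
        raise InvalidGeometryError("cannot resample a zero-length contour")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if contour.closed:
        # n_points samples around the loop, last one stops short of wrapping
        targets = np.linspace(0.0, total, n_points, endpoint=False)
    else:
        targets = np.linspace(0.0, total, n_points)
    x = np.interp(targets, s, chain[:, 0])
    y = np.interp(targets, s, chain[:, 1])
    return Contour(points=np.column_stack([x, y]), closed=contour.closed)


def center_of_mass(contour: Contour) -> np.ndarray:
    """Arc-length-weighted centroid of the contour (mm).

    Each segment contributes its midpoint weighted by its length, so the
    result is independent of point density. Open contours are closed by the
    chord between their endpoints first (the MV plane stands in for the
    missing wall), making the centre a property of the enclosed shape rather
    than of where the trace happens to start and stop.
    """
    pts = contour.points
    chain = np.vstack([pts, pts[:1]])  # chord closure (a real edge if already closed)
    d = np.diff(chain, axis=0)
    seg = np.linalg.norm(d, axis=1)
    mid = 0.5 * (chain[:-1] + chain[1:])
    total = float(seg.sum())
    if total <= 0.0:
        raise InvalidGeometryError("degenerate contour: zero total length")
    return (mid * seg[:, None]).sum(axis=0) / total


def segment_radii(
    contour: Contour,
    center: np.ndarray,
    n_segments: int = DEFAULT_N_SEGMENTS,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> np.ndarray:
    """Mean radius (mm) of each of ``n_segments`` contiguous wall segments.

    The contour is resampled to ``grid_points`` points and per-point distances
    to ``center`` are pooled into contiguous bins along the wall. With
    ``n_segments == grid_points`` this degenerates to per-point radii.
    """
    if n_segments < 1:
        raise InvalidInputError("n_segments must be >= 1")
    if n_segments > grid_points:
        raise InvalidInputError("n_segments cannot exceed the resampling grid size")
    center = np.asarray(center, dtype=float)
    res = resample_contour(contour, grid_points) if contour.n_points != grid_points else contour
    r = np.linalg.norm(res.points - center[None, :], axis=1)
    if np.any(r < 1e-9):
        raise InvalidGeometryError("a wall point coincides with the centre (zero radius)")
    bins = np.array_split(r, n_segments)
    return np.array([b.mean() for b in bins])
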