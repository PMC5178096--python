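import numpy as np
import pytest

from lastrain.geometry import Contour, ContourSequence


def circle_contour(radius=30.0, center=(0.0, 0.0), n=360, closed=True):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([
        center[0] + radius * np.cos(theta),
        center[1] + radius * np.sin(theta),
    ])
    return Contour(points=pts, closed=closed)


def random_polyline(rng, n=12, scale=20.0, closed=False):
    """Random star-shaped polygon around the origin (no self-intersections)."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(0.5 * scale, 1.5 * scale, n)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return Contour(points=pts, closed=closed)


def sequence_of_scalings(base: Contour, scales, cycle_ms=1000.0, about=None):
    """Frames produced by uniformly scaling ``base`` about ``about``.

    ``about`` defaults to the arc-length-weighted centroid computed
    independently here (midpoint-weighted segment sum with chord closure).
    """
    pts = base.points
    if about is None:
        chain = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        mid = 0.5 * (chain[:-1] + chain[1:])
        about = (mid * seg[:, None]).sum(axis=0) / seg.sum()
    about = np.asarray(about, dtype=float)
    frames = tuple(
        Contour(points=about + (1.0 + s) * (pts - about), closed=base.closed) for s in scales
    )
    times = np.linspace(0.0, cycle_ms, len(frames))
    return ContourSequence(frames=frames, times=times, view="4-chamber")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
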