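"""Per-frame pupil boundary estimation.

From a seed point inside the pupil, rays are cast at equal angular spacing
(default 12 rays, 30 degrees apart).  Image intensity is sampled along each
ray by bilinear interpolation and differentiated; because the pupil is the
darkest structure in the frame, the strongest *positive* (dark-to-bright)
gradient along a ray marks the pupil boundary.  Accepted edge points are
averaged into a radius estimate and fitted with a direct least-squares
ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.measure import EllipseModel

from .core import (
    EllipseFit,
    EllipseFitError,
    InsufficientPointsError,
    InvalidParameterError,
    NoEdgeError,
    SeedPoint,
)

__all__ = [
    "DetectConfig",
    "RayProfile",
    "EdgePointSet",
    "cast_rays",
    "detect_edge",
    "radius_from_edges",
    "fit_ellipse",
    "detect_pupil",
]


@dataclass(frozen=True)
class DetectConfig:
    """Ray-casting and edge-acceptance parameters.

    ``min_strength`` is the minimum dark-to-bright gradient (intensity units
    per pixel) for an edge candidate to count; the default was calibrated on
    rendered fixtures: the ideal edge gradient is ~0.19/px at default
    contrast while gradient noise is ~0.028/px at pixel noise 0.02, so 0.1
    sits ~3.6 noise sd below the shallowest genuine edge yet rejects
    occluded rays reliably.
    """

    n_rays: int = 12
    step_px: float = 1.0
    max_len_px: float = 60.0
    min_strength: float = 0.1


@dataclass
class RayProfile:
    """Sampled intensity and gradient along one ray from the seed."""

    angle_rad: float
    origin: SeedPoint
    sample_distances_px: np.ndarray
    intensities: np.ndarray
    gradient: np.ndarray
    gradient_distances_px: np.ndarray
    edge_distance_px: float | None = None
    edge_strength: float = 0.0


@dataclass
class EdgePointSet:
    """Accepted edge points for one frame plus an acceptance quality."""

    seed: SeedPoint
    points: np.ndarray  # (k, 3): x_px, y_px, strength
    n_rays: int
    quality: float


def cast_rays(
    frame: np.ndarray,
    seed: SeedPoint,
    n_rays: int = 12,
    max_len_px: float = 60.0,
    step_px: float = 1.0,
) -> list[RayProfile]:
    """Sample intensity along ``n_rays`` equally spaced rays from the seed.

    Rays point at angles ``2*pi*k/n_rays``; samples lie at distances
    ``step_px, 2*step_px, ... <= max_len_px`` (bilinear interpolation) and
    are truncated at the image border.  The gradient is the forward finite
    difference of the samples divided by ``step_px``; gradient sample ``i``
    is located midway between intensity samples ``i`` and ``i+1``.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise InvalidParameterError("frame must be 2-D grayscale")
    h, w = frame.shape
    seed.require_inside(h, w)
    if n_rays < 3:
        raise InvalidParameterError("need at least 3 rays")
    if step_px <= 0 or max_len_px <= 0:
        raise InvalidParameterError("step_px and max_len_px must be positive")

    distances = step_px * np.arange(1, int(max_len_px / step_px) + 1)
    angles = 2.0 * np.pi * np.arange(n_rays) / n_rays
    # all ray samples in one interpolation call
    xs = seed.x_px + np.outer(np.cos(angles), distances)
    ys = seed.y_px + np.outer(np.sin(angles), distances)
    inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    values = map_coordinates(
        frame,
        [ys.ravel(), xs.ravel()],
        order=1,
        mode="nearest",
    ).reshape(n_rays, -1)

    rays = []
    for k in range(n_rays):
        m = inside[k]
        # truncate at the first sample outside the border
        n_in = int(np.argmin(m)) if not m.all() else len(distances)
        d = distances[:n_in]
        vals = values[k, :n_in]
        grad = np.diff(vals) / step_px
        rays.append(
            RayProfile(
                angle_rad=float(angles[k]),
                origin=seed,
                sample_distances_px=d,
                intensities=vals,
                gradient=grad,
                gradient_distances_px=d[:-1] + step_px / 2.0 if n_in > 1 else d[:0],
            )
        )
    return rays


def _refine_parabolic(grad: np.ndarray, i: int) -> float:
    """Sub-sample offset of the gradient peak, in units of the step."""
    if i == 0 or i == len(grad) - 1:
        return 0.0
    denom = grad[i - 1] - 2.0 * grad[i] + grad[i + 1]
    if denom >= 0:  # not a proper maximum
        return 0.0
    delta = 0.5 * (grad[i - 1] - grad[i + 1]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def detect_edge(rays: Sequence[RayProfile], min_strength: float = 0.1) -> EdgePointSet:
    """Pick the strongest dark-to-bright gradient on each ray.

    The candidate on each ray is the sample maximising the signed gradient
    (pupil interior darker than iris); it is accepted when its strength
    reaches ``min_strength``.  Accepted candidates are refined to sub-sample
    precision by a three-point parabola and returned in image coordinates.
    Quality is the accepted fraction of rays; a quality of zero is a valid
    result, not an error.
    """
    if len(rays) == 0:
        raise InvalidParameterError("rays must be non-empty")
    seed = rays[0].origin
    pts = []
    for ray in rays:
        if len(ray.gradient) == 0:
            continue
        i = int(np.argmax(ray.gradient))
        strength = float(ray.gradient[i])
        if strength < min_strength:
            continue
        step = (
            ray.sample_distances_px[1] - ray.sample_distances_px[0]
            if len(ray.sample_distances_px) > 1
            else 1.0
        )
        d = float(ray.gradient_distances_px[i]) + _refine_parabolic(ray.gradient, i) * step
        ray.edge_distance_px = d
        ray.edge_strength = strength
        pts.append(
            (
                seed.x_px + d * np.cos(ray.angle_rad),
                seed.y_px + d * np.sin(ray.angle_rad),
                strength,
            )
        )
    points = np.asarray(pts, dtype=float).reshape(-1, 3)
    return EdgePointSet(
        seed=seed,
        points=points,
        n_rays=len(rays),
        quality=len(pts) / len(rays),
    )


def radius_from_edges(edges: EdgePointSet) -> float:
    """Mean Euclidean seed-to-edge distance (the averaged-length radius).

    The pupil diameter is twice this value.
    """
    if len(edges.points) == 0:
        raise NoEdgeError("no accepted edge points")
    d = np.hypot(
        edges.points[:, 0] - edges.seed.x_px,
        edges.points[:, 1] - edges.seed.y_px,
    )
    return float(d.mean())


def fit_ellipse(edges: EdgePointSet) -> EllipseFit:
    """Direct least-squares ellipse through the accepted edge points."""
    if len(edges.points) < 5:
        raise InsufficientPointsError(
            f"ellipse fit needs >= 5 points, got {len(edges.points)}"
        )
    xy = edges.points[:, :2]
    with np.errstate(divide="ignore"):  # perfect circles: a - c == 0 inside
        model = EllipseModel.from_estimate(xy)
    if not model:
        raise EllipseFitError("ellipse estimation failed")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])) or a <= 0 or b <= 0:
        raise EllipseFitError("degenerate ellipse solution")
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    theta = float(np.mod(theta, np.pi))
    return EllipseFit(
        center_x_px=float(xc),
        center_y_px=float(yc),
        semi_major_px=float(a),
        semi_minor_px=float(b),
        orientation_rad=theta,
    )


def detect_pupil(
    frame: np.ndarray,
    seed: SeedPoint,
    config: DetectConfig = DetectConfig(),
) -> tuple[EllipseFit | None, float]:
    """One-shot pupil detection: rays -> edges -> ellipse.

    Falls back to a circle (centre = edge-point centroid, radius = averaged
    seed-to-edge length) when the ellipse fit fails but at least three edge
    points exist.  Returns ``(None, 0.0)`` as a no-measurement sentinel when
    no edge is found; the tracker decides how to proceed.
    """
    rays = cast_rays(
        frame, seed, n_rays=config.n_rays,
        max_len_px=config.max_len_px, step_px=config.step_px,
    )
    edges = detect_edge(rays, min_strength=config.min_strength)
    if len(edges.points) == 0:
        return None, 0.0
    fit: EllipseFit | None = None
    if len(edges.points) >= 5:
        try:
            fit = fit_ellipse(edges)
        except (EllipseFitError, InsufficientPointsError):
            fit = None
    if fit is None and len(edges.points) >= 3:
        r = radius_from_edges(edges)
        fit = EllipseFit(
            center_x_px=float(edges.points[:, 0].mean()),
            center_y_px=float(edges.points[:, 1].mean()),
            semi_major_px=r,
            semi_minor_px=r,
            orientation_rad=0.0,
        )
    if fit is None:
        return None, edges.quality
    return fit, edges.quality
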