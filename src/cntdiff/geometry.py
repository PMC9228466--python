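"""Surface-local coordinate transforms for adsorbate trajectories.

An adsorbate above a plane or cylinder is described by three surface-local
coordinates: the axial arc coordinate ``s_par`` (along the CNT axis / the
armchair direction of graphene), the circumferential arc coordinate
``s_perp`` (around the tube / the zigzag direction), and the vertical
distance ``d`` to the closest point on the wall.  Displacement along
``s_par`` is the parallel (∥) component of surface diffusion; displacement
along ``s_perp`` is the perpendicular (⊥) component.

Circumferential arc length is measured, by default, at the trajectory-mean
radial distance of the tracked point (``rho_ref='mean'``): the adsorbate
travels on a cylinder of its own height above the wall, not on the wall
itself.  Passing ``rho_ref='wall'`` uses the wall radius instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import SurfaceSpec


class WrongSideError(ValueError):
    """The point lies on the opposite side of the surface from the adsorbate."""


class UnwrapAmbiguityError(ValueError):
    """Consecutive frames are too far apart for unambiguous unwrapping."""


@dataclass(frozen=True)
class SurfaceFrame:
    """Orthonormal tangent frame at the closest surface point.

    ``normal`` points toward the adsorbate side, ``tangent_par`` along the
    axis, ``tangent_perp`` along the circumference.
    """

    foot: np.ndarray
    normal: np.ndarray
    tangent_par: np.ndarray
    tangent_perp: np.ndarray


@dataclass
class UnwrappedPath:
    """Continuous surface-local coordinates of one tracked point.

    ``s_par`` and ``s_perp`` are free of periodic jumps; ``d`` is the
    vertical distance series (Å); ``times`` in ps.
    """

    times: np.ndarray
    s_par: np.ndarray
    s_perp: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.s_par = np.asarray(self.s_par, float)
        self.s_perp = np.asarray(self.s_perp, float)
        self.d = np.asarray(self.d, float)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def _nearest_groove_wall(points: np.ndarray, spec: SurfaceSpec) -> np.ndarray:
    """Index (0/1) of the closer cylinder for each point; ties keep index 0."""
    points = np.atleast_2d(points)
    dists = np.stack([
        np.abs(np.hypot(points[:, 0] - c[0], points[:, 1] - c[1]) - spec.radius)
        for c in spec.centers
    ], axis=1)
    return np.argmin(dists, axis=1)


def signed_vertical_distance(points: np.ndarray, spec: SurfaceSpec) -> np.ndarray:
    """Signed distance to the wall; positive on the declared adsorbate side.

    plane: z − z0; cylinder_exterior: ρ − R; cylinder_interior: R − ρ;
    groove: exterior rule applied to the nearer cylinder.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if spec.kind == "plane":
        return points[:, 2] - spec.centers[0, 2]
    if spec.kind in ("cylinder_exterior", "cylinder_interior"):
        c = spec.centers[0]
        rho = np.hypot(points[:, 0] - c[0], points[:, 1] - c[1])
        return rho - spec.radius if spec.kind == "cylinder_exterior" else spec.radius - rho
    # groove: min over both walls, exterior sign convention
    d_all = np.stack([
        np.hypot(points[:, 0] - c[0], points[:, 1] - c[1]) - spec.radius
        for c in spec.centers
    ], axis=1)
    idx = np.argmin(np.abs(d_all), axis=1)
    return d_all[np.arange(len(points)), idx]


def vertical_distance(point, spec: SurfaceSpec):
    """Distance from a point (or points) to its closest wall point, Å.

    Raises :class:`WrongSideError` if the point lies on the wrong side of
    the declared surface (e.g. an interior point for a
    ``cylinder_exterior`` spec).
    """
    arr = np.atleast_2d(np.asarray(point, float))
    d = signed_vertical_distance(arr, spec)
    if np.any(d < -1e-9):
        raise WrongSideError(
            f"point(s) at signed distance down to {d.min():.3f} Å lie on the "
            f"wrong side of the {spec.kind} surface")
    d = np.clip(d, 0.0, None)
    return float(d[0]) if np.asarray(point).ndim == 1 else d


def surface_frame(point, spec: SurfaceSpec) -> SurfaceFrame:
    """Closest surface point and orthonormal tangent frame at a point."""
    p = np.asarray(point, float)
    if spec.kind == "plane":
        foot = np.array([p[0], p[1], spec.centers[0, 2]])
        return SurfaceFrame(foot, np.array([0.0, 0.0, 1.0]),
                            np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
    if spec.kind == "groove":
        wall = int(_nearest_groove_wall(p[None, :], spec)[0])
        c = spec.centers[wall]
        inward = False
    else:
        c = spec.centers[0]
        inward = spec.kind == "cylinder_interior"
    radial = np.array([p[0] - c[0], p[1] - c[1], 0.0])
    rho = np.linalg.norm(radial)
    if rho < 1e-12:
        raise ValueError("point lies on the cylinder axis: frame undefined")
    rho_hat = radial / rho
    foot = np.array([c[0], c[1], p[2]]) + spec.radius * rho_hat
    normal = -rho_hat if inward else rho_hat
    t_par = np.array([0.0, 0.0, 1.0])
    t_perp = np.cross(normal, t_par)
    return SurfaceFrame(foot, normal, t_par, t_perp)


def unwrap_axis(coords, period: float) -> np.ndarray:
    """Remove periodic jumps from a scalar coordinate series.

    Consecutive differences become minimum-image differences; the first
    value is preserved.  Steps of exactly period/2 are ambiguous and
    resolved toward the negative image (numpy convention).
    """
    coords = np.asarray(coords, float)
    if period <= 0:
        raise ValueError("period must be positive")
    return np.unwrap(coords, period=period)


_AMBIGUITY_FRACTION = 0.45


def _unwrap_checked(coords, period: float, what: str) -> np.ndarray:
    # Minimum-image steps approaching period/2 cannot be distinguished
    # from their opposite image: treat them as under-sampled frames.
    out = np.unwrap(np.asarray(coords, float), period=period)
    steps = np.abs(np.diff(out))
    if steps.size and steps.max() > _AMBIGUITY_FRACTION * period:
        raise UnwrapAmbiguityError(
            f"{what}: frame-to-frame step {steps.max():.3g} is close to half "
            f"the period {period:.3g}; frames are too sparse to unwrap")
    return out


def decompose_path(points: np.ndarray, spec: SurfaceSpec, box=None,
                   times=None, rho_ref: str | float = "mean") -> UnwrappedPath:
    """Decompose a tracked point's trajectory into (s_par, s_perp, d).

    Parameters
    ----------
    points:
        (n_frames, 3) positions (may be wrapped into the box).
    box:
        Periodic box lengths; defaults to ``spec.box``.
    times:
        Frame times in ps; defaults to the frame index.
    rho_ref:
        Radius used to convert the unwrapped cylindrical angle to the
        circumferential arc length: ``'mean'`` (trajectory-mean radial
        distance of the point, default), ``'wall'`` (the wall radius), or
        an explicit value in Å.

    For a plane this is exactly Cartesian unwrapping of the two in-plane
    components.  For a groove the majority-occupied wall is used as the
    reference cylinder and the angular origin is the groove midline.
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must have shape (n_frames, 3)")
    box = spec.box if box is None else np.asarray(box, float)
    times = np.arange(len(points), dtype=float) if times is None else np.asarray(times, float)

    if spec.kind == "plane":
        s_par = _unwrap_checked(points[:, 0], box[0], "x")
        s_perp = _unwrap_checked(points[:, 1], box[1], "y")
        d = points[:, 2] - spec.centers[0, 2]
        return UnwrappedPath(times, s_par, s_perp, d)

    if spec.kind == "groove":
        walls = _nearest_groove_wall(points, spec)
        wall = int(np.round(walls.mean()))  # majority wall
        center = spec.centers[wall]
        # groove midline faces the other tube
        other = spec.centers[1 - wall]
        origin_angle = np.arctan2(other[1] - center[1], other[0] - center[0])
        interior = False
    else:
        center = spec.centers[0]
        origin_angle = 0.0
        interior = spec.kind == "cylinder_interior"

    s_par = _unwrap_checked(points[:, 2], box[2], "axial")
    dx = points[:, 0] - center[0]
    dy = points[:, 1] - center[1]
    rho = np.hypot(dx, dy)
    angle = np.arctan2(dy, dx) - origin_angle
    angle = _unwrap_checked(angle, 2.0 * np.pi, "angle")
    if rho_ref == "mean":
        rref = float(rho.mean())
    elif rho_ref == "wall":
        rref = float(spec.radius)
    else:
        rref = float(rho_ref)
    s_perp = rref * angle
    d = (spec.radius - rho) if interior else (rho - spec.radius)
    if spec.kind == "groove":
        d = signed_vertical_distance(points, spec)
    return UnwrappedPath(times, s_par, s_perp, d)


def wrap_coords(coords: np.ndarray, box: np.ndarray,
                periodic=(True, True, True)) -> np.ndarray:
    """Wrap coordinates into [0, L) along the periodic directions."""
    out = np.array(coords, float, copy=True)
    for k in range(3):
        if periodic[k]:
            out[..., k] %= box[k]
    return out


def minimum_image(delta: np.ndarray, box: np.ndarray,
                  periodic=(True, True, True)) -> np.ndarray:
    """Minimum-image convention applied to displacement vectors."""
    out = np.array(delta, float, copy=True)
    for k in range(3):
        if periodic[k]:
            out[..., k] -= box[k] * np.round(out[..., k] / box[k])
    return out
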