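"""Builders for periodic graphene sheets, single-walled CNTs, and CNT grooves.

All surfaces are hexagonal carbon lattices with a fixed C–C bond length
``a_cc`` (default 1.4180 Å, chosen so that 41 armchair translational cells
give a 100.698 Å tube and a 40 x 23 rectangular graphene supercell gives a
98.2419 x 97.8420 Å² sheet).  Surface atoms are treated as immobile, so a
built :class:`Structure` carries only species, coordinates, and the
periodic box.

Conventions
-----------
* CNT axis: +z.  Graphene sheet: the z = z0 plane, adsorbate side +z.
* The rectangular graphene cell is (sqrt(3)·a_cc) x (3·a_cc) with 4 atoms;
  x runs along the armchair direction, y along the zigzag direction.
* Armchair (n,n) tubes roll the zigzag direction around the circumference
  (4n atoms per axial period sqrt(3)·a_cc); zigzag (0,m) tubes roll the
  armchair direction (4m atoms per axial period 3·a_cc).
* Groove: two identical parallel tubes, axes along z, wall-to-wall gap
  ``gap`` (default 3.4 Å, the C···C van der Waals contact), midplane x = cx.
  The angular origin of each tube faces the other tube (the groove midline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_A_CC = 1.4180
#: Wall-to-wall distance of two CNTs in van der Waals contact, Å.
DEFAULT_GROOVE_GAP = 3.4

_KINDS = ("plane", "cylinder_interior", "cylinder_exterior", "groove")


@dataclass(frozen=True)
class LatticeParams:
    """Hexagonal-lattice geometry: the carbon–carbon bond length in Å."""

    a_cc: float = DEFAULT_A_CC

    def __post_init__(self):
        if self.a_cc <= 0:
            raise ValueError(f"a_cc must be positive, got {self.a_cc}")


@dataclass(frozen=True)
class SurfaceSpec:
    """Analytic description of a carbon surface.

    Parameters
    ----------
    kind:
        One of ``plane``, ``cylinder_interior``, ``cylinder_exterior``,
        ``groove``.
    radius:
        Cylinder radius in Å (cylinder/groove kinds).
    centers:
        Anchor points, shape (k, 3): a point in the plane, one point on the
        cylinder axis, or the two axis points of a groove.
    box:
        Periodic box lengths (Lx, Ly, Lz) in Å.
    periodic:
        Periodicity flags per box direction.
    gap:
        Wall-to-wall distance of the two groove cylinders, Å (groove only).
    axis:
        Cylinder axis direction; only +z is supported.
    """

    kind: str
    centers: np.ndarray
    box: np.ndarray
    periodic: tuple[bool, bool, bool] = (False, False, True)
    radius: float | None = None
    gap: float | None = None
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown surface kind {self.kind!r}")
        object.__setattr__(self, "centers", np.atleast_2d(np.asarray(self.centers, float)))
        object.__setattr__(self, "box", np.asarray(self.box, float))
        if tuple(self.axis) != (0.0, 0.0, 1.0):
            raise NotImplementedError("only the +z axis convention is supported")
        if self.kind in ("cylinder_interior", "cylinder_exterior", "groove"):
            if self.radius is None or self.radius <= 0:
                raise ValueError("cylinder kinds require radius > 0")
        if self.kind == "groove":
            if len(self.centers) != 2:
                raise ValueError("groove requires exactly two axis centers")
            if abs(self.centers[0, 2] - self.centers[1, 2]) > 1e-9:
                raise ValueError("groove cylinders must be parallel (equal z anchor)")
        elif len(self.centers) != 1:
            raise ValueError(f"{self.kind} requires exactly one anchor point")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")

    # ---- convenience constructors -------------------------------------
    @staticmethod
    def plane(z0: float, box) -> "SurfaceSpec":
        box = np.asarray(box, float)
        return SurfaceSpec("plane", centers=[[0.0, 0.0, z0]], box=box,
                           periodic=(True, True, False))

    @staticmethod
    def cylinder(radius: float, kind: str, center_xy, box) -> "SurfaceSpec":
        cx, cy = center_xy
        return SurfaceSpec(kind, centers=[[cx, cy, 0.0]], box=np.asarray(box, float),
                           periodic=(False, False, True), radius=radius)

    @staticmethod
    def two_cylinder_groove(radius: float, gap: float, centers_xy, box) -> "SurfaceSpec":
        centers = [[x, y, 0.0] for x, y in centers_xy]
        return SurfaceSpec("groove", centers=centers, box=np.asarray(box, float),
                           periodic=(False, False, True), radius=radius, gap=gap)


@dataclass
class Structure:
    """A built surface: per-atom species and coordinates plus the box."""

    species: list[str]
    coords: np.ndarray
    box: np.ndarray
    periodic: tuple[bool, bool, bool]
    spec: SurfaceSpec = field(repr=False, default=None)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.box = np.asarray(self.box, float)
        if len(self.species) != len(self.coords):
            raise ValueError("species and coords length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


def cnt_radius(n: int, m: int, a_cc: float = DEFAULT_A_CC) -> float:
    """Radius of an (n, m) CNT: sqrt(3)·a_cc·sqrt(n² + n·m + m²) / (2π)."""
    if n < 0 or m < 0:
        raise ValueError("chiral indices must be non-negative")
    if n == 0 and m == 0:
        raise ValueError("chiral indices (0, 0) do not define a tube")
    return np.sqrt(3.0) * a_cc * np.sqrt(n * n + n * m + m * m) / (2.0 * np.pi)


def _graphene_points(n_armchair: int, n_zigzag: int, a_cc: float) -> tuple[np.ndarray, float, float]:
    """2D honeycomb points in an (n_armchair·sqrt(3)a) x (n_zigzag·3a) rectangle."""
    lx = np.sqrt(3.0) * a_cc
    ly = 3.0 * a_cc
    base = np.array([
        [0.0, 0.0],
        [lx / 2.0, a_cc / 2.0],
        [lx / 2.0, 3.0 * a_cc / 2.0],
        [0.0, 2.0 * a_cc],
    ])
    ii, jj = np.meshgrid(np.arange(n_armchair), np.arange(n_zigzag), indexing="ij")
    offsets = np.stack([ii.ravel() * lx, jj.ravel() * ly], axis=1)
    pts = (offsets[:, None, :] + base[None, :, :]).reshape(-1, 2)
    return pts, n_armchair * lx, n_zigzag * ly


def build_graphene(n_armchair_repeats: int, n_zigzag_repeats: int,
                   a_cc: float = DEFAULT_A_CC, height: float = 60.0) -> Structure:
    """Periodic flat graphene sheet in the z = 0 plane.

    The box is (sqrt(3)·a_cc·n_armchair, 3·a_cc·n_zigzag, height) with 4
    atoms per rectangular cell; (40, 23) repeats give the 98.2419 x
    97.8420 Å² production sheet.
    """
    if n_armchair_repeats < 1 or n_zigzag_repeats < 1:
        raise ValueError("repeat counts must be >= 1")
    pts, lx, ly = _graphene_points(n_armchair_repeats, n_zigzag_repeats, a_cc)
    coords = np.column_stack([pts, np.zeros(len(pts))])
    box = np.array([lx, ly, height])
    spec = SurfaceSpec.plane(0.0, box)
    return Structure(["C"] * len(coords), coords, box, (True, True, False), spec)


def _roll(pts: np.ndarray, circumference: float, center_xy=(0.0, 0.0)) -> np.ndarray:
    """Roll 2D lattice points (circumferential, axial) onto a z-axis cylinder."""
    radius = circumference / (2.0 * np.pi)
    theta = 2.0 * np.pi * pts[:, 0] / circumference
    return np.column_stack([
        center_xy[0] + radius * np.cos(theta),
        center_xy[1] + radius * np.sin(theta),
        pts[:, 1],
    ])


def _cnt_points(n: int, m: int, n_cells: int, a_cc: float) -> tuple[np.ndarray, float, float]:
    """(circumferential, axial) lattice points for an armchair or zigzag tube."""
    if n == m and n > 0:  # armchair: zigzag direction around the circumference
        pts, axial_len, circ = _graphene_points(n_cells, n, a_cc)
        return pts[:, ::-1], circ, axial_len
    if n == 0 and m > 0:  # zigzag: armchair direction around the circumference
        pts, circ, axial_len = _graphene_points(m, n_cells, a_cc)
        return pts, circ, axial_len
    if n == 0 and m == 0:
        raise ValueError("chiral indices (0, 0) do not define a tube")
    raise NotImplementedError(
        f"only armchair (n,n) and zigzag (0,m) tubes are supported, got ({n},{m})")


def build_cnt(n: int, m: int, n_cells: int, a_cc: float = DEFAULT_A_CC,
              margin: float = 15.0, kind: str = "cylinder_exterior") -> Structure:
    """Single-walled armchair (n,n) or zigzag (0,m) CNT, axis +z.

    ``n_cells`` counts axial translational periods: sqrt(3)·a_cc for
    armchair (41 cells -> 100.698 Å) and 3·a_cc for zigzag.  ``kind``
    selects which side of the wall the surface spec declares as the
    adsorbate side.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    pts, circ, axial_len = _cnt_points(n, m, n_cells, a_cc)
    radius = circ / (2.0 * np.pi)
    lateral = 2.0 * radius + 2.0 * margin
    center = (lateral / 2.0, lateral / 2.0)
    coords = _roll(pts, circ, center)
    box = np.array([lateral, lateral, axial_len])
    spec = SurfaceSpec.cylinder(radius, kind, center, box)
    return Structure(["C"] * len(coords), coords, box, (False, False, True), spec)


def build_groove(n: int, n_cells: int, gap: float = DEFAULT_GROOVE_GAP,
                 a_cc: float = DEFAULT_A_CC, margin: float = 15.0) -> Structure:
    """Two parallel armchair (n,n) CNTs forming a one-dimensional groove.

    Axes run along z at center-to-center distance 2·radius + gap; the
    default gap of 3.4 Å is the van der Waals contact of the two walls.
    """
    pts, circ, axial_len = _cnt_points(n, n, n_cells, a_cc)
    radius = circ / (2.0 * np.pi)
    if gap <= -2.0 * radius:
        raise ValueError("gap <= -2·radius: tubes would overlap completely")
    half_sep = radius + gap / 2.0
    lx = 4.0 * radius + 2.0 * abs(gap) + 2.0 * margin
    ly = 2.0 * radius + 2.0 * margin
    cy = ly / 2.0
    centers = [(lx / 2.0 - half_sep, cy), (lx / 2.0 + half_sep, cy)]
    coords = np.vstack([_roll(pts, circ, c) for c in centers])
    box = np.array([lx, ly, axial_len])
    spec = SurfaceSpec.two_cylinder_groove(radius, gap, centers, box)
    return Structure(["C"] * len(coords), coords, box, (False, False, True), spec)
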