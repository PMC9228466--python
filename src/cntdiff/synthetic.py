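"""Synthetic trajectory generators with known ground truth.

Every estimator in the package is validated against data generated here:
the generators emulate the *statistical* structure of adsorbate MD on
carbon surfaces — anisotropic Brownian surface motion, a rigid
dopamine-like multi-site adsorbate with configurable vertical / tilt /
orientation distributions, a layered solvent above the wall, and Poisson
wall-switching in a CNT groove — without any force field or integrator.

All generators are seed-deterministic: the same seed yields bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import MoietyMap
from .geometry import UnwrappedPath, surface_frame, wrap_coords
from .structures import DEFAULT_GROOVE_GAP, SurfaceSpec, cnt_radius
from .trajio import Trajectory
from .units import ATOMIC_MASSES, diffusion_to_internal

#: Default adsorbate height above the wall, Å (van der Waals contact).
DEFAULT_HEIGHT = 3.4


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianMixture1D:
    """Weighted 1D Gaussian mixture; a zero width makes a delta component."""

    weights: tuple[float, ...]
    centers: tuple[float, ...]
    widths: tuple[float, ...]

    def __post_init__(self):
        if not len(self.weights) == len(self.centers) == len(self.widths):
            raise ValueError("weights, centers, widths must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    @staticmethod
    def delta(value: float) -> "GaussianMixture1D":
        return GaussianMixture1D((1.0,), (value,), (0.0,))

    def sample(self, rng: np.random.Generator, n: int,
               low: float | None = None, high: float | None = None) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        out = np.asarray(self.centers)[comp] + \
            np.asarray(self.widths)[comp] * rng.standard_normal(n)
        if low is not None or high is not None:
            out = np.clip(out, low, high)
        return out


def _sticky_series(values: np.ndarray, rng: np.random.Generator,
                   dt: float, corr_time: float) -> np.ndarray:
    """Impose an exponential correlation time by sticky resampling.

    Each frame keeps the previous value with probability exp(−dt/τ),
    otherwise takes the next independent draw — the marginal distribution
    is preserved exactly while introducing time correlation.
    """
    if corr_time <= 0:
        return values
    n = len(values)
    refresh = rng.random(n) < -np.expm1(-dt / corr_time)
    refresh[0] = True
    idx = np.maximum.accumulate(np.where(refresh, np.arange(n), -1))
    return values[idx]


# ---------------------------------------------------------------------------
# anisotropic surface Brownian motion
# ---------------------------------------------------------------------------

@dataclass
class BrownianParams:
    """Overdamped anisotropic Brownian motion on a surface.

    ``D_par`` / ``D_perp`` in 1e-5 cm²/s, ``dt`` in ps.  The walker moves
    at a fixed height ``height`` above the wall; on cylinders the
    circumferential arc is traced at the walker's own radius R ± height.
    """

    D_par: float
    D_perp: float
    dt: float
    n_steps: int
    seed: int
    surface: SurfaceSpec
    height: float = DEFAULT_HEIGHT
    s_par0: float = 0.0
    s_perp0: float = 0.0
    groove_wall: int = 0

    def __post_init__(self):
        if self.D_par < 0 or self.D_perp < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def _walker_geometry(spec: SurfaceSpec, height: float, wall: int):
    """(center_xy, walker radius, angle origin) for cylindrical kinds."""
    if spec.kind == "groove":
        c = spec.centers[wall]
        other = spec.centers[1 - wall]
        origin = np.arctan2(other[1] - c[1], other[0] - c[0])
        return c, spec.radius + height, origin
    c = spec.centers[0]
    if spec.kind == "cylinder_interior":
        return c, spec.radius - height, 0.0
    return c, spec.radius + height, 0.0


def surface_path_to_coords(s_par: np.ndarray, s_perp: np.ndarray,
                           spec: SurfaceSpec, height, wall: int = 0) -> np.ndarray:
    """Map surface-local coordinates (+ height above the wall) to 3D points."""
    height = np.broadcast_to(np.asarray(height, float), s_par.shape)
    if spec.kind == "plane":
        z0 = spec.centers[0, 2]
        return np.column_stack([s_par, s_perp, z0 + height])
    c, rho_w, origin = _walker_geometry(spec, float(height[0]), wall)
    sign = -1.0 if spec.kind == "cylinder_interior" else 1.0
    rho = spec.radius + sign * height
    theta = origin + s_perp / rho_w
    return np.column_stack([c[0] + rho * np.cos(theta),
                            c[1] + rho * np.sin(theta), s_par])


def simulate_surface_brownian(p: BrownianParams) -> tuple[UnwrappedPath, Trajectory]:
    """Euler–Maruyama surface random walk with prescribed D∥ and D⊥.

    Returns the exact unwrapped ground-truth path and the wrapped 3D
    single-site trajectory it induces on the surface.
    """
    rng = np.random.default_rng(p.seed)
    sig_par = np.sqrt(2.0 * diffusion_to_internal(p.D_par) * p.dt)
    sig_perp = np.sqrt(2.0 * diffusion_to_internal(p.D_perp) * p.dt)
    n = p.n_steps
    s_par = p.s_par0 + np.concatenate([[0.0], np.cumsum(sig_par * rng.standard_normal(n))])
    s_perp = p.s_perp0 + np.concatenate([[0.0], np.cumsum(sig_perp * rng.standard_normal(n))])
    times = np.arange(n + 1) * p.dt
    d = np.full(n + 1, p.height)
    path = UnwrappedPath(times, s_par, s_perp, d)
    coords = surface_path_to_coords(s_par, s_perp, p.surface, p.height, p.groove_wall)
    coords = wrap_coords(coords[:, None, :], p.surface.box, p.surface.periodic)
    traj = Trajectory(times, coords, ["X"], p.surface.box, roles=["adsorbate"],
                      timestep=p.dt)
    return path, traj


# ---------------------------------------------------------------------------
# rigid dopamine-like adsorbate
# ---------------------------------------------------------------------------

@dataclass
class AdsorbateModel:
    """Rigid multi-site adsorbate with stochastic placement.

    ``template`` holds the site coordinates in the molecular frame (the
    C2→C7 vector along +x, the ring plane in xy); ``d_dist`` is the
    vertical-distance distribution of the amine COM, ``tilt_dist`` the
    tilt angle φ (degrees, signed), ``orient_dist`` the in-plane azimuth θ
    (degrees) of the backbone against the axial direction.  ``corr_time``
    (ps) gives all three series an exponential memory; 0 makes frames
    independent.
    """

    template: np.ndarray
    species: list[str]
    moieties: MoietyMap
    d_dist: GaussianMixture1D = field(default_factory=lambda: GaussianMixture1D.delta(3.5))
    tilt_dist: GaussianMixture1D = field(default_factory=lambda: GaussianMixture1D.delta(0.0))
    orient_dist: GaussianMixture1D = field(default_factory=lambda: GaussianMixture1D.delta(0.0))
    corr_time: float = 1.0


def dopamine_like() -> tuple[np.ndarray, list[str], MoietyMap]:
    """Idealized rigid dopamine geometry (heavy atoms + amine hydrogens).

    A planar template: 6-carbon aromatic ring (C1–C6, hexagon of radius
    1.40 Å), two diol oxygens on C4/C5, the side-chain carbon C7 placed so
    |C2−C7| = 3.8 Å along +x, and an amine group (N + 2 H) beyond it.
    Site order: ring(0–5), O(6), O(7), C7(8), N(9), H(10), H(11).
    """
    r_ring = 1.40
    angles = np.radians(np.arange(6) * 60.0)
    ring = np.column_stack([r_ring * np.cos(angles), r_ring * np.sin(angles),
                            np.zeros(6)])
    r_o = r_ring + 1.36
    oxy = np.array([[r_o * np.cos(np.radians(120)), r_o * np.sin(np.radians(120)), 0.0],
                    [r_o * np.cos(np.radians(180)), r_o * np.sin(np.radians(180)), 0.0]])
    c7 = np.array([[ring[0, 0] + 3.8, 0.0, 0.0]])
    n_pos = c7[0] + np.array([1.2, 0.8, 0.0])
    amine = np.array([n_pos,
                      n_pos + np.array([0.6, 0.8, 0.0]),
                      n_pos + np.array([0.95, -0.3, 0.0])])
    template = np.vstack([ring, oxy, c7, amine])
    species = ["C"] * 6 + ["O", "O", "C", "N", "H", "H"]
    masses = np.array([ATOMIC_MASSES[s] for s in species])
    moieties = MoietyMap(ring=list(range(6)), diol_or_quinone=[6, 7],
                         amine=[9, 10, 11], c2=0, c7=8, masses=masses)
    return template, species, moieties


def simulate_adsorbate(model: AdsorbateModel, base_path: UnwrappedPath,
                       spec: SurfaceSpec, seed: int = 0) -> Trajectory:
    """Place the rigid adsorbate along a base surface path.

    At each frame the molecule is oriented with backbone azimuth θ in the
    local tangent plane, tilted by φ toward the surface normal, and
    translated so the amine COM sits at vertical distance d on the normal
    through the path point.  d, φ, θ are drawn from the model's
    distributions (with the model's correlation time).

    On planes the resulting descriptor values (amine d, tilt φ, and — for
    φ = 0 — orientation θ) reproduce the drawn values exactly; on
    cylinders the tangent frame varies over the molecule so tilt and
    orientation are recovered to within the molecular-size/radius ratio.
    """
    rng = np.random.default_rng(seed)
    n = len(base_path)
    dt = base_path.dt if n > 1 else 1.0
    d_ser = _sticky_series(model.d_dist.sample(rng, n, low=0.5), rng, dt, model.corr_time)
    # +-90 deg would make the in-plane frame degenerate
    phi_ser = _sticky_series(model.tilt_dist.sample(rng, n, low=-89.9, high=89.9),
                             rng, dt, model.corr_time)
    th_ser = _sticky_series(model.orient_dist.sample(rng, n), rng, dt, model.corr_time)

    amine_local = np.average(model.template[model.moieties.amine], axis=0,
                             weights=model.moieties.masses[model.moieties.amine])
    coords = np.empty((n, len(model.template), 3))
    feet = surface_path_to_coords(base_path.s_par, base_path.s_perp, spec,
                                  np.zeros(n))
    for i in range(n):
        if spec.kind == "plane":
            normal = np.array([0.0, 0.0, 1.0])
            t_par = np.array([1.0, 0.0, 0.0])
            t_perp = np.array([0.0, 1.0, 0.0])
        else:
            fr = surface_frame(feet[i], spec)
            normal, t_par, t_perp = fr.normal, fr.tangent_par, fr.tangent_perp
        phi = np.radians(phi_ser[i])
        th = np.radians(th_ser[i])
        e1 = np.cos(phi) * (np.cos(th) * t_par + np.sin(th) * t_perp) + np.sin(phi) * normal
        e3 = normal - np.dot(normal, e1) * e1
        e3 /= np.linalg.norm(e3)
        e2 = np.cross(e3, e1)
        rot = np.column_stack([e1, e2, e3])
        origin = feet[i] + d_ser[i] * normal - rot @ amine_local
        coords[i] = model.template @ rot.T + origin
    coords = wrap_coords(coords, spec.box, spec.periodic)
    roles = ["adsorbate"] * len(model.species)
    return Trajectory(base_path.times, coords, list(model.species), spec.box,
                      roles=roles, timestep=dt)


# ---------------------------------------------------------------------------
# layered solvent
# ---------------------------------------------------------------------------

@dataclass
class SolventModel:
    """Layered water density above the wall (oxygen sites only).

    ``layer_centers`` / ``layer_widths`` / ``layer_amplitudes`` describe
    Gaussian density layers (amplitudes in molecules/Å³); beyond
    ``bulk_start`` a uniform bulk of ``bulk_density`` fills up to the
    sampling ceiling.  Defaults emulate interfacial water: layers at 3.3 Å
    and 6.2 Å above the carbon wall, with amplitudes calibrated so the
    first hydration shell of the reference adsorbate holds roughly 26–33
    waters at the 5 Å cutoff.
    """

    layer_centers: tuple[float, ...] = (3.3, 6.2)
    layer_widths: tuple[float, ...] = (0.45, 0.70)
    layer_amplitudes: tuple[float, ...] = (0.064, 0.041)
    bulk_density: float = 0.025
    bulk_start: float = 7.5

    def __post_init__(self):
        if any(c <= 0 for c in self.layer_centers):
            raise ValueError("layer centers must be positive")
        if list(self.layer_centers) != sorted(self.layer_centers):
            raise ValueError("layer centers must increase")

    def density(self, d: np.ndarray) -> np.ndarray:
        """Volume number density of water oxygens at vertical distance d."""
        d = np.asarray(d, float)
        out = np.zeros_like(d)
        for a, mu, sig in zip(self.layer_amplitudes, self.layer_centers,
                              self.layer_widths):
            out += a * np.exp(-0.5 * ((d - mu) / sig) ** 2)
        out += np.where(d >= self.bulk_start, self.bulk_density, 0.0)
        return out


def simulate_solvent(model: SolventModel, spec: SurfaceSpec, n_frames: int,
                     seed: int = 0, d_max: float = 12.0) -> Trajectory:
    """Independent frames of water oxygens from the layered density.

    Vertical positions follow ``model.density`` (weighted by the
    cylindrical shell area so the *volume* density is as prescribed);
    lateral positions are uniform on the surface.  Frames are independent
    — there is no water dynamics, which suffices for every structural
    descriptor.  The per-frame count is the rounded expectation, constant
    across frames.
    """
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, d_max, 0.02)
    dd = grid[1] - grid[0]
    mid = grid + dd / 2.0
    dens = model.density(mid)
    if spec.kind == "plane":
        area = spec.box[0] * spec.box[1]
        shell = np.full_like(mid, area)
    else:
        sign = -1.0 if spec.kind == "cylinder_interior" else 1.0
        shell = 2.0 * np.pi * np.clip(spec.radius + sign * mid, 0.0, None) * spec.box[2]
    w = dens * shell * dd
    lam = w.sum()
    n_water = int(round(lam))
    if n_water == 0:
        raise ValueError("solvent model yields zero waters for this surface")
    prob = w / lam
    frames = np.empty((n_frames, n_water, 3))
    for i in range(n_frames):
        d = mid[rng.choice(len(mid), size=n_water, p=prob)] + \
            (rng.random(n_water) - 0.5) * dd
        if spec.kind == "plane":
            x = rng.random(n_water) * spec.box[0]
            y = rng.random(n_water) * spec.box[1]
            z = spec.centers[0, 2] + d
            frames[i] = np.column_stack([x, y, z])
        else:
            sign = -1.0 if spec.kind == "cylinder_interior" else 1.0
            theta = rng.random(n_water) * 2.0 * np.pi
            rho = spec.radius + sign * d
            c = spec.centers[0]
            frames[i] = np.column_stack([c[0] + rho * np.cos(theta),
                                         c[1] + rho * np.sin(theta),
                                         rng.random(n_water) * spec.box[2]])
    times = np.arange(n_frames, dtype=float)
    return Trajectory(times, frames, ["O"] * n_water, spec.box,
                      roles=["water"] * n_water)


# ---------------------------------------------------------------------------
# groove wall switching
# ---------------------------------------------------------------------------

def default_groove_spec(margin: float = 15.0) -> SurfaceSpec:
    """Two (15,15)-tube groove spec (radius 10.16 Å, 3.4 Å gap, 100.7 Å box)."""
    radius = cnt_radius(15, 15)
    gap = DEFAULT_GROOVE_GAP
    half = radius + gap / 2.0
    lx = 4.0 * radius + 2.0 * gap + 2.0 * margin
    ly = 2.0 * radius + 2.0 * margin
    cy = ly / 2.0
    box = np.array([lx, ly, 100.698])
    return SurfaceSpec.two_cylinder_groove(
        radius, gap, [(lx / 2.0 - half, cy), (lx / 2.0 + half, cy)], box)


def simulate_wall_switching(rate: float, duration_ns: float, dt_ps: float,
                            seed: int = 0, spec: SurfaceSpec | None = None,
                            height: float = DEFAULT_HEIGHT,
                            seat_angle_deg: float = 40.0,
                            jitter_deg: float = 3.0,
                            D_axial: float = 1.82):
    """Poisson wall-to-wall switching of a groove-seated adsorbate.

    The adsorbate sits at ``seat_angle_deg`` off the groove midline on one
    wall (AR-jittered), diffuses axially with ``D_axial`` (1e-5 cm²/s),
    and swaps walls as a Poisson process of the given rate (events/ns);
    swapped positions are mirrored across the groove midplane.

    Returns ``(labels, trajectory, spec)`` where ``labels`` is the exact
    ground-truth wall sequence.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    from .groove import WallLabels  # local import to avoid a cycle

    if spec is None:
        spec = default_groove_spec()
    rng = np.random.default_rng(seed)
    n = int(round(duration_ns * 1000.0 / dt_ps)) + 1
    times = np.arange(n) * dt_ps

    # Poisson swap times -> per-frame wall label
    labels = np.zeros(n, dtype=int)
    if rate > 0:
        t = 0.0
        cur = 0
        swap_times = []
        while True:
            t += rng.exponential(1000.0 / rate)  # mean waiting time in ps
            if t >= times[-1]:
                break
            swap_times.append(t)
        cur = 0
        j = 0
        for i, ti in enumerate(times):
            while j < len(swap_times) and swap_times[j] <= ti:
                cur ^= 1
                j += 1
            labels[i] = cur

    sig_z = np.sqrt(2.0 * diffusion_to_internal(D_axial) * dt_ps)
    z = np.concatenate([[0.0], np.cumsum(sig_z * rng.standard_normal(n - 1))])
    ang = np.radians(seat_angle_deg + jitter_deg * rng.standard_normal(n))

    cA = spec.centers[0]
    other = spec.centers[1]
    mid = np.arctan2(other[1] - cA[1], other[0] - cA[0])
    rho = spec.radius + height
    xa = cA[0] + rho * np.cos(mid + ang)
    ya = cA[1] + rho * np.sin(mid + ang)
    midplane_x = 0.5 * (spec.centers[0, 0] + spec.centers[1, 0])
    x = np.where(labels == 1, 2.0 * midplane_x - xa, xa)
    coords = np.column_stack([x, ya, z])
    coords = wrap_coords(coords[:, None, :], spec.box, spec.periodic)
    traj = Trajectory(times, coords, ["X"], spec.box, roles=["adsorbate"],
                      timestep=dt_ps)
    da = np.abs(np.hypot(coords[:, 0, 0] - spec.centers[0, 0],
                         coords[:, 0, 1] - spec.centers[0, 1]) - spec.radius)
    db = np.abs(np.hypot(coords[:, 0, 0] - spec.centers[1, 0],
                         coords[:, 0, 1] - spec.centers[1, 1]) - spec.radius)
    return WallLabels(times, labels, da, db), traj, spec
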