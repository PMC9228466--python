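"""Structural descriptors of an adsorbate above a carbon surface.

The adsorbate (a dopamine-like molecule) is partitioned into moieties —
the aromatic ring, the diol/quinone oxygens, and the amine tail — via a
:class:`MoietyMap` of atom indices.  The descriptors are:

* vertical distance ``d`` of a moiety's center of mass to the nearest wall
  point, summarized as a histogram and a k-Gaussian peak fit;
* tilt angle φ of the C2–C7 backbone vector against the local tangent
  plane, signed toward the surface normal (φ > 0 when C7 is farther from
  the wall than C2);
* axial orientation θ between the C2–C7 vector and the tube axis, wrapped
  into [0°, 90°] because the two axial directions are equivalent;
* lateral distributions folded into a small number of graphene unit cells;
* the first-hydration-shell count N_water (waters whose oxygen is within a
  cutoff, 5 Å by default, of any adsorbate atom and on the adsorbate's
  side of the wall), and the vertical water density profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .geometry import minimum_image, signed_vertical_distance, surface_frame
from .structures import SurfaceSpec

#: First-hydration-shell cutoff, Å.
DEFAULT_HYDRATION_CUTOFF = 5.0
#: Histogram bin widths matching the analysis defaults.
DEFAULT_LATERAL_BIN = 0.1      # Å
DEFAULT_TILT_BIN = 0.36        # degrees
DEFAULT_ORIENTATION_BIN = 3.6  # degrees


class FitFailureError(RuntimeError):
    """Gaussian peak fit did not converge."""


@dataclass
class MoietyMap:
    """Atom-index bookkeeping for the adsorbate's chemical moieties.

    ``c2`` is the ring carbon and ``c7`` the side-chain carbon whose
    connecting vector defines tilt and orientation; ``c2`` must belong to
    the ring and ``c7`` must not.
    """

    ring: list[int]
    diol_or_quinone: list[int]
    amine: list[int]
    c2: int
    c7: int
    masses: np.ndarray

    def __post_init__(self):
        self.masses = np.asarray(self.masses, float)
        if len(self.ring) != 6:
            raise ValueError("ring must contain exactly 6 atom indices")
        if self.c2 not in self.ring:
            raise ValueError("c2 must be a ring atom")
        if self.c7 in self.ring:
            raise ValueError("c7 must not be a ring atom")
        if set(self.ring) & set(self.diol_or_quinone) or set(self.ring) & set(self.amine):
            raise ValueError("ring indices overlap another moiety")

    def indices(self, which: str) -> list[int]:
        try:
            return {"ring": self.ring, "diol_or_quinone": self.diol_or_quinone,
                    "amine": self.amine, "all": list(range(len(self.masses)))}[which]
        except KeyError:
            raise ValueError(f"unknown moiety {which!r}") from None


@dataclass
class Histogram1D:
    """Normalized 1D histogram: ``density`` integrates to 1 over ``edges``."""

    edges: np.ndarray
    density: np.ndarray
    counts: np.ndarray = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @staticmethod
    def from_samples(values, bin_width: float, range_=None,
                     weights=None) -> "Histogram1D":
        values = np.asarray(values, float)
        if range_ is None:
            lo, hi = values.min(), values.max()
            lo = np.floor(lo / bin_width) * bin_width
            hi = np.ceil(hi / bin_width) * bin_width + bin_width
        else:
            lo, hi = range_
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(values, bins=edges, weights=weights)
        total = counts.sum()
        if total <= 0:
            raise ValueError("histogram is empty")
        density = counts / (total * bin_width)
        return Histogram1D(edges, density, counts)


@dataclass
class Histogram2D:
    """Normalized 2D histogram: bin probabilities ``density`` sum to 1."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray
    counts: np.ndarray = None


@dataclass
class PeakFit:
    """k-Gaussian mixture description of a 1D density.

    ``centers`` are sorted ascending; ``weights`` are the mixture
    fractions (area shares); ``goodness`` is the residual 2-norm.
    """

    centers: np.ndarray
    widths: np.ndarray
    weights: np.ndarray
    goodness: float


def make_whole(frame: np.ndarray, box, periodic=(True, True, True)) -> np.ndarray:
    """Reconnect a molecule split by periodic wrapping.

    Every site is minimum-imaged relative to the first site, so
    intramolecular vectors (e.g. C2–C7) are correct afterwards.  Valid
    while the molecule is smaller than half the box.
    """
    frame = np.asarray(frame, float)
    ref = frame[0]
    return ref + minimum_image(frame - ref, np.asarray(box, float), periodic)


def moiety_com(frame: np.ndarray, moieties: MoietyMap, which: str,
               box=None, periodic=(True, True, True)) -> np.ndarray:
    """Mass-weighted center of a moiety, minimum-imaged within the moiety.

    Member atoms are made whole relative to the first member before
    averaging, so a moiety split across a periodic boundary is handled
    correctly.  The returned point may lie outside [0, box).
    """
    frame = np.asarray(frame, float)
    idx = moieties.indices(which)
    if max(idx) >= len(frame):
        raise ValueError(f"moiety index {max(idx)} outside frame of {len(frame)} sites")
    pos = frame[idx]
    masses = moieties.masses[idx]
    if box is not None:
        ref = pos[0]
        pos = ref + minimum_image(pos - ref, np.asarray(box, float), periodic)
    return np.average(pos, axis=0, weights=masses)


def tilt_angle(c2, c7, spec: SurfaceSpec) -> float:
    """Signed tilt φ of the C2→C7 vector against the surface, degrees.

    φ is the angle between the vector and its projection onto the tangent
    plane at the surface foot of the vector's midpoint, in [−90°, 90°],
    positive when C7 sits farther from the wall than C2.
    """
    c2 = np.asarray(c2, float)
    c7 = np.asarray(c7, float)
    v = c7 - c2
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("C2 and C7 coincide: tilt undefined")
    frame = surface_frame(0.5 * (c2 + c7), spec)
    return float(np.degrees(np.arcsin(np.clip(np.dot(v / norm, frame.normal), -1, 1))))


def axial_orientation(c2, c7, axis=(0.0, 0.0, 1.0)) -> float:
    """Orientation θ of the C2→C7 vector against the tube axis, degrees.

    The raw angle in [0°, 180°] is wrapped to [0°, 90°] (θ → 180° − θ for
    θ > 90°): the two axial directions are physically equivalent.
    """
    v = np.asarray(c7, float) - np.asarray(c2, float)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("C2 and C7 coincide: orientation undefined")
    axis = np.asarray(axis, float)
    cosang = np.clip(np.dot(v / norm, axis / np.linalg.norm(axis)), -1, 1)
    theta = float(np.degrees(np.arccos(cosang)))
    return 180.0 - theta if theta > 90.0 else theta


def lateral_distribution(s_par, s_perp, cell: tuple[float, float],
                         bin_width: float = DEFAULT_LATERAL_BIN,
                         n_cells: int = 4) -> Histogram2D:
    """Lateral density folded into ``n_cells`` x ``n_cells`` surface cells.

    ``cell`` is the rectangular surface unit cell (axial, circumferential)
    in Å — (sqrt(3)·a_cc, 3·a_cc) for the honeycomb lattice.  Probabilities
    sum to 1.
    """
    cx, cy = cell
    if bin_width > min(cx, cy) * n_cells:
        raise ValueError("bin width exceeds the folded cell")
    lx, ly = n_cells * cx, n_cells * cy
    x = np.asarray(s_par, float) % lx
    y = np.asarray(s_perp, float) % ly
    # tile the folded cell exactly (bin width adjusted by < one part in nbins)
    x_edges = np.linspace(0.0, lx, max(1, round(lx / bin_width)) + 1)
    y_edges = np.linspace(0.0, ly, max(1, round(ly / bin_width)) + 1)
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=[x_edges, y_edges])
    total = counts.sum()
    if total <= 0:
        raise ValueError("no samples")
    return Histogram2D(x_edges, y_edges, counts / total, counts)


def vertical_distribution(d_series, bin_width: float = 0.05,
                          range_=None) -> Histogram1D:
    """Histogram of vertical distances d (Å), density integrating to 1."""
    return Histogram1D.from_samples(d_series, bin_width, range_)


def _gaussian_mixture(x, *params):
    out = np.zeros_like(x)
    for i in range(len(params) // 3):
        a, mu, sig = params[3 * i:3 * i + 3]
        out += a * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return out


def fit_peaks(hist: Histogram1D, k: int, centers_guess=None) -> PeakFit:
    """Least-squares k-Gaussian fit of a 1D density.

    Initial centers come from ``centers_guess`` or from the ``k`` most
    prominent local maxima of the histogram.  Raises
    :class:`FitFailureError` if the optimizer fails or too few peaks can
    be seeded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = hist.centers
    y = hist.density
    if centers_guess is None:
        order = find_peaks(y, prominence=0.0)[0]
        if len(order) < k:
            # fall back to the k tallest bins, spaced at least 2 bins apart
            order = np.argsort(y)[::-1]
        prominences = y[order]
        centers_guess = np.sort(x[order[np.argsort(prominences)[::-1][:k]]])
    centers_guess = np.sort(np.asarray(centers_guess, float))
    if len(centers_guess) != k:
        raise FitFailureError(f"could not seed {k} peaks (found {len(centers_guess)})")
    span = x[-1] - x[0]
    p0 = []
    for c in centers_guess:
        p0 += [float(np.interp(c, x, y)), float(c), max(span / (6.0 * k), hist.bin_width)]
    lower = [0.0, x[0] - span, 1e-4] * k
    upper = [np.inf, x[-1] + span, span] * k
    try:
        params, _ = curve_fit(_gaussian_mixture, x, y, p0=p0,
                              bounds=(lower, upper), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"Gaussian mixture fit failed: {exc}") from exc
    params = np.asarray(params).reshape(k, 3)
    amp, mu, sig = params.T
    areas = amp * sig * np.sqrt(2.0 * np.pi)
    if areas.sum() > 1.0:  # fit of a normalized density: clamp to fractions
        areas = areas / areas.sum()
    order = np.argsort(mu)
    resid = float(np.linalg.norm(y - _gaussian_mixture(x, *params.ravel())))
    return PeakFit(mu[order], sig[order], areas[order], resid)


def _pairwise_min_dist(targets: np.ndarray, sources: np.ndarray,
                       box=None, periodic=(True, True, True)) -> np.ndarray:
    """Minimum distance of each target point to any source point."""
    delta = targets[:, None, :] - sources[None, :, :]
    if box is not None:
        delta = minimum_image(delta, np.asarray(box, float), periodic)
    return np.sqrt((delta ** 2).sum(axis=2)).min(axis=1)


def hydration_count(adsorbate: np.ndarray, water_oxygens: np.ndarray,
                    spec: SurfaceSpec, cutoff: float = DEFAULT_HYDRATION_CUTOFF,
                    box=None, periodic=(True, True, True)) -> int:
    """Number of first-shell waters around the adsorbate.

    A water counts when its oxygen's minimum distance to any adsorbate
    atom is at most ``cutoff`` *and* it sits on the adsorbate's side of
    the wall (interior vs exterior vs above the sheet) — solvent on the
    far side of the surface cannot solvate the adsorbate.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    water_oxygens = np.atleast_2d(np.asarray(water_oxygens, float))
    if water_oxygens.size == 0:
        return 0
    adsorbate = np.atleast_2d(np.asarray(adsorbate, float))
    same_side = signed_vertical_distance(water_oxygens, spec) >= 0.0
    dmin = _pairwise_min_dist(water_oxygens, adsorbate, box, periodic)
    return int(np.count_nonzero(same_side & (dmin <= cutoff)))


def water_density_profile(frames, spec: SurfaceSpec, bin_width: float = 0.1,
                          d_max: float | None = None) -> Histogram1D:
    """Vertical density profile of water oxygens, shell-volume corrected.

    For cylindrical surfaces the accessible volume of the shell at
    distance d scales with (R ± d); each sample is weighted by the inverse
    so a uniform volume filling yields a flat profile.  The returned
    density is normalized to integrate to 1.
    """
    frames = np.asarray(frames, float)
    pts = frames.reshape(-1, 3)
    d = signed_vertical_distance(pts, spec)
    keep = d >= 0
    d = d[keep]
    if d.size == 0:
        raise ValueError("no water on the adsorbate side of the surface")
    if spec.kind == "plane":
        w = None
    else:
        sign = -1.0 if spec.kind == "cylinder_interior" else 1.0
        w = 1.0 / np.clip(spec.radius + sign * d, 1e-6, None)
    rng = (0.0, d_max) if d_max is not None else None
    return Histogram1D.from_samples(d, bin_width, rng, weights=w)
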