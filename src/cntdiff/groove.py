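"""Dynamics of an adsorbate in the groove between two parallel CNTs.

The groove — the concave channel where two aligned tubes nearly touch —
confines an adsorbate: circumferential motion is blocked by the second
wall while axial motion remains free.  This module labels each frame by
the nearer wall, estimates the rate of wall-to-wall jumps, detects entry
into (and retention within) the groove, and builds 2D/3D occupancy maps
of the confined adsorbate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import Histogram2D
from .geometry import _nearest_groove_wall, unwrap_axis
from .structures import DEFAULT_A_CC, SurfaceSpec

#: Minimum persistence of a wall change to count as a jump, ps.
DEFAULT_DEBOUNCE_PS = 1.0
#: A frame is "in the groove" when both wall distances are below this, Å.
DEFAULT_GROOVE_CUTOFF = 8.0

WALL_A, WALL_B = 0, 1


@dataclass
class WallLabels:
    """Per-frame nearest-wall assignment with both wall distances (Å)."""

    times: np.ndarray
    label: np.ndarray          # 0 = wall_A, 1 = wall_B
    min_dist_A: np.ndarray
    min_dist_B: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.label = np.asarray(self.label, int)

    @property
    def duration_ns(self) -> float:
        return float(self.times[-1] - self.times[0]) / 1000.0


@dataclass
class JumpEstimate:
    """Wall-to-wall jump statistics: rate = n_events / duration."""

    rate: float       # events / ns
    n_events: int
    duration: float   # ns
    error: float      # events / ns (Poisson, sqrt(n)/T)


@dataclass
class GrooveEntry:
    """First groove-entry time and whether the adsorbate stayed."""

    entered: bool
    entry_time_ns: float | None
    retained: bool


def _wall_distances(frames: np.ndarray, spec: SurfaceSpec) -> tuple[np.ndarray, np.ndarray]:
    """Minimum atom-to-wall distance per frame for each groove cylinder.

    ``frames`` is (n_frames, n_atoms, 3) or (n_frames, 3) for a single
    tracked site.  Distances are unsigned (to the wall surface).
    """
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[:, None, :]
    out = []
    for c in spec.centers:
        rho = np.hypot(frames[..., 0] - c[0], frames[..., 1] - c[1])
        out.append(np.abs(rho - spec.radius).min(axis=1))
    return out[0], out[1]


def assign_wall(frames: np.ndarray, spec: SurfaceSpec, times=None) -> WallLabels:
    """Label each frame by the nearer groove wall.

    The nearest wall is the one with the smaller minimum adsorbate-atom-
    to-wall distance; exact ties keep the previous frame's label (the
    first frame breaks a tie toward wall A).
    """
    if spec.kind != "groove":
        raise ValueError("assign_wall requires a groove surface spec")
    da, db = _wall_distances(frames, spec)
    n = len(da)
    times = np.arange(n, dtype=float) if times is None else np.asarray(times, float)
    raw = np.where(da < db, WALL_A, np.where(db < da, WALL_B, -1))
    if raw[0] == -1:
        raw[0] = WALL_A
    # ties (-1) inherit the most recent decided label
    decided = np.where(raw != -1, np.arange(n), -1)
    labels = raw[np.maximum.accumulate(decided)]
    return WallLabels(times, labels, da, db)


def jump_rate(labels: WallLabels, debounce: float = DEFAULT_DEBOUNCE_PS) -> JumpEstimate:
    """Rate of wall-to-wall jumps that persist at least ``debounce`` ps.

    Runs of the new label shorter than the debounce time are treated as
    chatter and merged into the surrounding run.  With ``debounce=0``
    every label change counts, an upper bound for any positive debounce.
    The error is the Poisson estimate sqrt(n)/T.
    """
    t = labels.times
    duration_ns = labels.duration_ns
    if duration_ns <= 0:
        raise ValueError("trajectory duration must be positive")
    lab = labels.label
    # run-length encode
    change = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(lab)]])
    # keep runs lasting >= debounce (last run always kept: persistence
    # unobserved beyond the trajectory end, counted as persisting)
    kept = []
    for s, e in zip(starts, ends):
        span = t[e - 1] - t[s]
        if span >= debounce or s == 0 or e == len(lab):
            kept.append(lab[s])
    n_events = int(np.count_nonzero(np.diff(np.array(kept))) if len(kept) > 1 else 0)
    rate = n_events / duration_ns
    return JumpEstimate(rate=rate, n_events=n_events, duration=duration_ns,
                        error=float(np.sqrt(n_events)) / duration_ns)


def groove_entry(frames: np.ndarray, spec: SurfaceSpec, times=None,
                 cutoff: float = DEFAULT_GROOVE_CUTOFF) -> GrooveEntry:
    """First time the adsorbate is within ``cutoff`` of *both* walls.

    Returns the entry time (ns) and whether the in-groove condition holds
    for every later frame.  A trajectory that never enters yields
    ``entered=False`` (not an error).
    """
    da, db = _wall_distances(frames, spec)
    n = len(da)
    times = np.arange(n, dtype=float) if times is None else np.asarray(times, float)
    inside = (da <= cutoff) & (db <= cutoff)
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        return GrooveEntry(False, None, False)
    first = idx[0]
    return GrooveEntry(True, float(times[first]) / 1000.0, bool(inside[first:].all()))


def occupancy_maps(frames: np.ndarray, spec: SurfaceSpec,
                   bin_width: float = 0.1, n_cells: int = 2,
                   cell_length: float | None = None,
                   grid_bin: float = 0.5):
    """2D (axial x circumferential) and 3D occupancy of a groove adsorbate.

    The axial coordinate is wrapped into ``n_cells`` surface unit cells of
    length ``cell_length`` (default: the armchair lattice period
    sqrt(3)·a_cc for the standard bond length).  The
    circumferential coordinate is the arc distance from the groove
    midline, negative on wall A's side and positive on wall B's, so a
    two-wall trajectory shows a bimodal split at 0.

    Returns ``(Histogram2D, (edges, counts3d))``; both normalized to 1.
    """
    frames = np.asarray(frames, float)
    pts = frames if frames.ndim == 2 else frames.mean(axis=1)
    walls = _nearest_groove_wall(pts, spec)
    cell = np.sqrt(3.0) * DEFAULT_A_CC if cell_length is None else cell_length
    lz = n_cells * cell
    axial = pts[:, 2] % lz

    perp = np.empty(len(pts))
    for w in (WALL_A, WALL_B):
        mask = walls == w
        if not mask.any():
            continue
        c = spec.centers[w]
        other = spec.centers[1 - w]
        mid = np.arctan2(other[1] - c[1], other[0] - c[0])
        ang = np.arctan2(pts[mask, 1] - c[1], pts[mask, 0] - c[0]) - mid
        ang = (ang + np.pi) % (2.0 * np.pi) - np.pi
        rho = np.hypot(pts[mask, 0] - c[0], pts[mask, 1] - c[1])
        arc = rho * np.abs(ang)
        perp[mask] = -arc if w == WALL_A else arc

    x_edges = np.linspace(0.0, lz, max(1, round(lz / bin_width)) + 1)
    pmax = np.abs(perp).max() + bin_width
    ny = max(1, round(2 * pmax / bin_width))
    y_edges = np.linspace(-pmax, pmax, ny + 1)
    counts, x_edges, y_edges = np.histogram2d(axial, perp, bins=[x_edges, y_edges])
    hist2d = Histogram2D(x_edges, y_edges, counts / counts.sum(), counts)

    edges3 = [np.arange(0.0, spec.box[k] + grid_bin / 2, grid_bin) for k in range(3)]
    wrapped = pts.copy()
    wrapped[:, 2] %= spec.box[2]
    counts3, edges3 = np.histogramdd(wrapped, bins=edges3)
    return hist2d, (edges3, counts3 / counts3.sum())
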