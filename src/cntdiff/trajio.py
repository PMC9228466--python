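"""Plain-text trajectory and structure I/O: LAMMPS dump, LAMMPS data, XYZ.

Coordinates are stored in Å.  Site indices are 0-based in memory and
1-based in LAMMPS-facing files, following the LAMMPS convention.  All
readers accept a path or an open text stream and raise
:class:`ParseError` carrying the offending line number on malformed
input; all writers emit text that the corresponding reader parses back
losslessly at the written precision.
"""

from __future__ import annotations

import io
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np

from .structures import Structure, SurfaceSpec
from .units import ATOMIC_MASSES


class ParseError(ValueError):
    """Malformed input; ``line`` is the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass
class Trajectory:
    """Time-ordered frames of site coordinates.

    ``coords`` has shape (n_frames, n_sites, 3) in Å; ``labels`` are
    element symbols per site; ``roles`` optionally mark sites as
    adsorbate / water oxygen / surface carbon; ``times`` in ps must be
    strictly increasing.
    """

    times: np.ndarray
    coords: np.ndarray
    labels: list[str]
    box: np.ndarray
    roles: list[str] | None = None
    timestep: float | None = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.coords = np.asarray(self.coords, float)
        self.box = np.asarray(self.box, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_sites, 3)")
        if self.coords.shape[0] != len(self.times):
            raise ValueError("times and coords frame counts differ")
        if self.coords.shape[1] != len(self.labels):
            raise ValueError("labels must match the per-frame site count")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.timestep is None and len(self.times) > 1:
            self.timestep = float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coords.shape[1]

    def site_coords(self, index: int) -> np.ndarray:
        """(n_frames, 3) series of one site."""
        return self.coords[:, index, :]


@contextmanager
def _as_stream(source, mode: str):
    if hasattr(source, "read") or hasattr(source, "write"):
        yield source
    else:
        with open(source, mode) as fh:
            yield fh


class _Lines:
    """Line iterator tracking the 1-based line number."""

    def __init__(self, stream):
        self._it = iter(stream)
        self.n = 0

    def next(self, what: str) -> str:
        try:
            line = next(self._it)
        except StopIteration:
            raise ParseError(f"unexpected end of file while reading {what}", self.n) from None
        self.n += 1
        return line.rstrip("\n")


# ---------------------------------------------------------------------------
# LAMMPS dump
# ---------------------------------------------------------------------------

def write_lammps_dump(traj: Trajectory, dest, type_map: dict[str, int] | None = None,
                      precision: int = 6) -> None:
    """Write a text LAMMPS dump (``id type element x y z`` columns).

    Frame ``i`` is written with integer timestep ``i``; the physical
    frame spacing is carried by ``traj.timestep`` and must be supplied to
    the reader (dump files store only integer step numbers).
    """
    if type_map is None:
        type_map = {el: i + 1 for i, el in enumerate(dict.fromkeys(traj.labels))}
    fmt = f"{{:d}} {{:d}} {{}} {{:.{precision}f}} {{:.{precision}f}} {{:.{precision}f}}\n"
    with _as_stream(dest, "w") as fh:
        for i in range(traj.n_frames):
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{i}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{traj.n_sites}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for k in range(3):
                fh.write(f"0.0 {traj.box[k]:.{precision}f}\n")
            fh.write("ITEM: ATOMS id type element x y z\n")
            for j in range(traj.n_sites):
                x, y, z = traj.coords[i, j]
                fh.write(fmt.format(j + 1, type_map[traj.labels[j]],
                                    traj.labels[j], x, y, z))


def read_lammps_dump(source, timestep: float = 1.0,
                     element_of_type: dict[int, str] | None = None) -> Trajectory:
    """Parse a text LAMMPS dump into a :class:`Trajectory`.

    Understands unscaled (``x y z``) and scaled (``xs ys zs``) coordinate
    columns; scaled coordinates are unscaled with the box bounds.  Frame
    times are ``step * timestep`` (ps).  An optional ``element`` column
    supplies site labels; otherwise ``element_of_type`` maps the integer
    type, falling back to the label ``T<type>``.
    """
    frames, times = [], []
    labels = None
    box = None
    with _as_stream(source, "r") as fh:
        lines = _Lines(fh)
        while True:
            try:
                header = lines.next("frame header")
            except ParseError:
                break  # clean end of file
            if not header.startswith("ITEM: TIMESTEP"):
                raise ParseError(f"expected 'ITEM: TIMESTEP', got {header!r}", lines.n)
            try:
                step = int(lines.next("timestep value").split()[0])
            except (ValueError, IndexError):
                raise ParseError("timestep value is not an integer", lines.n) from None
            if not lines.next("atom-count header").startswith("ITEM: NUMBER OF ATOMS"):
                raise ParseError("expected 'ITEM: NUMBER OF ATOMS'", lines.n)
            try:
                n_atoms = int(lines.next("atom count"))
            except ValueError:
                raise ParseError("atom count is not an integer", lines.n) from None
            bounds_header = lines.next("box header")
            if not bounds_header.startswith("ITEM: BOX BOUNDS"):
                raise ParseError("expected 'ITEM: BOX BOUNDS'", lines.n)
            lo = np.empty(3)
            hi = np.empty(3)
            for k in range(3):
                parts = lines.next("box bounds").split()
                try:
                    lo[k], hi[k] = float(parts[0]), float(parts[1])
                except (ValueError, IndexError):
                    raise ParseError("malformed box bounds", lines.n) from None
            box = hi - lo
            atoms_header = lines.next("atoms header")
            if not atoms_header.startswith("ITEM: ATOMS"):
                raise ParseError("expected 'ITEM: ATOMS'", lines.n)
            columns = atoms_header.split()[2:]
            col = {name: i for i, name in enumerate(columns)}
            scaled = "xs" in col
            names = ("xs", "ys", "zs") if scaled else ("x", "y", "z")
            if not all(name in col for name in names):
                raise ParseError(f"dump must contain x y z or xs ys zs columns, "
                                 f"got {columns}", lines.n)
            if "id" not in col:
                raise ParseError("dump must contain an 'id' column", lines.n)
            coords = np.empty((n_atoms, 3))
            frame_labels = [None] * n_atoms
            for _ in range(n_atoms):
                parts = lines.next("atom record").split()
                if len(parts) != len(columns):
                    raise ParseError(
                        f"atom record has {len(parts)} fields, expected {len(columns)}",
                        lines.n)
                try:
                    aid = int(parts[col["id"]]) - 1
                    xyz = [float(parts[col[c]]) for c in names]
                except ValueError:
                    raise ParseError("non-numeric atom record", lines.n) from None
                if not 0 <= aid < n_atoms:
                    raise ParseError(f"atom id {aid + 1} out of range", lines.n)
                coords[aid] = np.asarray(xyz) * box + lo if scaled else xyz
                if "element" in col:
                    frame_labels[aid] = parts[col["element"]]
                elif "type" in col:
                    t = int(parts[col["type"]])
                    frame_labels[aid] = (element_of_type or {}).get(t, f"T{t}")
                else:
                    frame_labels[aid] = "X"
            if labels is None:
                labels = frame_labels
            elif labels != frame_labels:
                raise ParseError("site labels changed between frames", lines.n)
            frames.append(coords)
            times.append(step * timestep)
    if not frames:
        raise ParseError("empty dump: no frames found", 0)
    return Trajectory(np.array(times), np.array(frames), labels, box,
                      timestep=timestep)


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, dest, precision: int = 6) -> None:
    """Multi-frame XYZ; the comment line carries ``time=`` and ``box=``."""
    fmt = f"{{}} {{:.{precision}f}} {{:.{precision}f}} {{:.{precision}f}}\n"
    with _as_stream(dest, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{traj.n_sites}\n")
            bx = " ".join(f"{b:.{precision}f}" for b in traj.box)
            fh.write(f"time={traj.times[i]:.6f} box={bx}\n")
            for j in range(traj.n_sites):
                fh.write(fmt.format(traj.labels[j], *traj.coords[i, j]))


def read_xyz(source, box=None) -> Trajectory:
    """Parse a (multi-frame) XYZ file.

    ``time=`` and ``box=`` annotations on the comment line are honored
    when present; otherwise frame times default to the frame index and
    ``box`` must be supplied.
    """
    frames, times, labels = [], [], None
    file_box = None
    with _as_stream(source, "r") as fh:
        lines = _Lines(fh)
        while True:
            try:
                count_line = lines.next("atom count")
            except ParseError:
                break
            if not count_line.strip():
                continue
            try:
                n_atoms = int(count_line.split()[0])
            except ValueError:
                raise ParseError(f"expected an atom count, got {count_line!r}",
                                 lines.n) from None
            comment = lines.next("comment line")
            t = float(len(frames))
            for tok in comment.split():
                if tok.startswith("time="):
                    t = float(tok[5:])
                elif tok.startswith("box="):
                    pass
            if "box=" in comment:
                vals = comment.split("box=")[1].split()[:3]
                file_box = np.array([float(v) for v in vals])
            coords = np.empty((n_atoms, 3))
            frame_labels = []
            for a in range(n_atoms):
                parts = lines.next("atom line").split()
                if len(parts) < 4:
                    raise ParseError("atom line needs 'element x y z'", lines.n)
                frame_labels.append(parts[0])
                try:
                    coords[a] = [float(v) for v in parts[1:4]]
                except ValueError:
                    raise ParseError("non-numeric coordinates", lines.n) from None
            if labels is None:
                labels = frame_labels
            elif labels != frame_labels:
                raise ParseError("site labels changed between frames", lines.n)
            frames.append(coords)
            times.append(t)
    if not frames:
        raise ParseError("empty XYZ file", 0)
    box = file_box if file_box is not None else box
    if box is None:
        box = np.full(3, np.inf)
    return Trajectory(np.array(times), np.array(frames), labels, np.asarray(box, float))


# ---------------------------------------------------------------------------
# LAMMPS data (atom-style atomic)
# ---------------------------------------------------------------------------

def write_lammps_data(struct: Structure, dest, precision: int = 6) -> None:
    """Write a LAMMPS data file (atom_style atomic) for a built structure."""
    types = list(dict.fromkeys(struct.species))
    type_of = {el: i + 1 for i, el in enumerate(types)}
    with _as_stream(dest, "w") as fh:
        fh.write("LAMMPS data file (cntdiff)\n\n")
        fh.write(f"{struct.n_atoms} atoms\n")
        fh.write(f"{len(types)} atom types\n\n")
        for k, ax in enumerate("xyz"):
            fh.write(f"0.0 {struct.box[k]:.{precision}f} {ax}lo {ax}hi\n")
        fh.write("\nMasses\n\n")
        for el in types:
            fh.write(f"{type_of[el]} {ATOMIC_MASSES.get(el, 1.0):.4f}  # {el}\n")
        fh.write("\nAtoms  # atomic\n\n")
        for i, (el, xyz) in enumerate(zip(struct.species, struct.coords)):
            fh.write(f"{i + 1} {type_of[el]} "
                     + " ".join(f"{v:.{precision}f}" for v in xyz) + "\n")


def read_lammps_data(source, element_of_type: dict[int, str] | None = None) -> Structure:
    """Parse a LAMMPS data file (atom_style atomic) into a Structure."""
    with _as_stream(source, "r") as fh:
        text = fh.read()
    if not text.strip():
        raise ParseError("empty data file", 0)
    lines = text.splitlines()
    n_atoms = None
    box = np.zeros(3)
    masses: dict[int, float] = {}
    atoms: list[tuple[int, int, float, float, float]] = []
    section = None
    for ln, raw in enumerate(lines[1:], start=2):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if line.endswith("atoms"):
            n_atoms = int(line.split()[0])
        elif line.endswith("atom types"):
            pass
        elif line.endswith(("xlo xhi", "ylo yhi", "zlo zhi")):
            k = "xyz".index(line.split()[-2][0])
            lo, hi = float(line.split()[0]), float(line.split()[1])
            box[k] = hi - lo
        elif line.startswith("Masses"):
            section = "masses"
        elif line.startswith("Atoms"):
            section = "atoms"
        elif section == "masses":
            t, m = line.split()[:2]
            masses[int(t)] = float(m)
        elif section == "atoms":
            parts = line.split()
            if len(parts) < 5:
                raise ParseError("atom record needs 'id type x y z'", ln)
            try:
                atoms.append((int(parts[0]), int(parts[1]),
                              float(parts[2]), float(parts[3]), float(parts[4])))
            except ValueError:
                raise ParseError("non-numeric atom record", ln) from None
    if n_atoms is None or not atoms:
        raise ParseError("no atoms found in data file", 0)
    if len(atoms) != n_atoms:
        raise ParseError(f"atom count mismatch: header {n_atoms}, found {len(atoms)}", 0)
    mass_to_el = {round(m, 2): el for el, m in ATOMIC_MASSES.items()}
    species = [""] * n_atoms
    coords = np.empty((n_atoms, 3))
    for aid, atype, x, y, z in atoms:
        if element_of_type and atype in element_of_type:
            el = element_of_type[atype]
        else:
            el = mass_to_el.get(round(masses.get(atype, -1.0), 2), f"T{atype}")
        species[aid - 1] = el
        coords[aid - 1] = (x, y, z)
    return Structure(species, coords, box, (True, True, True), None)


def structure_to_xyz(struct: Structure, dest) -> None:
    """Single-frame XYZ for a built structure."""
    traj = Trajectory(np.array([0.0]), struct.coords[None, :, :],
                      list(struct.species), struct.box)
    write_xyz(traj, dest)


def dumps_xyz(struct: Structure) -> str:
    buf = io.StringIO()
    structure_to_xyz(struct, buf)
    return buf.getvalue()
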