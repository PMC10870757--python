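"""Trajectory containers and text coordinate I/O (GRO, PDB, XYZ).

Internal length unit is Angstrom everywhere; GRO files (nm) are converted at
the boundary.  Only orthorhombic boxes are supported: triclinic input is
rejected with an explicit error.

Format notes
------------
GRO      fixed-width GROMACS format, nm, 3 decimals; multiple frames may be
         concatenated in one file; the title line may carry ``t= <ps>``
         (GROMACS convention), converted to ns.
PDB      multi-frame via MODEL/ENDMDL; box from CRYST1 (one per file, angles
         must be 90); coordinates in Angstrom; frame times are frame indices.
XYZ      extended dialect: the per-frame comment line carries
         ``time=<ns> box="lx ly lz"`` (Angstrom); the box entry is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .topology import Topology

__all__ = [
    "Frame",
    "Trajectory",
    "ParseError",
    "StructuralError",
    "read_coordinates",
    "write_coordinates",
]

_FORMATS = ("gro", "pdb", "xyz")


class ParseError(ValueError):
    """Malformed coordinate record; message names the offending line."""


class StructuralError(ValueError):
    """Structurally inconsistent trajectory (bead counts, boxes, times)."""


@dataclass
class Frame:
    """One snapshot: bead positions (Angstrom), box lengths, time (ns)."""

    time: float
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if not np.all(self.box > 0):
            raise StructuralError("box lengths must be strictly positive")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def copy(self) -> "Frame":
        return Frame(self.time, self.positions.copy(), self.box.copy())


@dataclass
class Trajectory:
    """Topology plus time-ordered frames with a constant bead count."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self):
        if len(self.frames) == 0:
            raise StructuralError("trajectory must contain at least one frame")
        n = self.topology.n_beads
        for i, fr in enumerate(self.frames):
            if fr.n_beads != n:
                raise StructuralError(
                    f"frame {i} has {fr.n_beads} beads, topology has {n}"
                )
        times = np.array([fr.time for fr in self.frames])
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise StructuralError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def positions_array(self) -> np.ndarray:
        """Stacked (n_frames, n_beads, 3) coordinate array."""
        return np.stack([fr.positions for fr in self.frames])

    def sliced(self, start: int, stop: int | None = None) -> "Trajectory":
        return Trajectory(self.topology, [fr.copy() for fr in self.frames[start:stop]])


# ---------------------------------------------------------------------------
# format detection
# ---------------------------------------------------------------------------

def _resolve_format(path, fmt: str | None) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported coordinate format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def read_coordinates(path, format: str | None = None) -> list[Frame]:
    """Read all frames of a text coordinate file.

    Coordinates are converted to Angstrom (GRO nm -> A); frame times are
    taken from the file where the dialect carries them, otherwise the frame
    index is used.  Raises :class:`ParseError` naming the line for malformed
    records and :class:`StructuralError` for inconsistent frames.
    """
    fmt = _resolve_format(path, format)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise ParseError(f"{path}: empty coordinate file")
    reader = {"gro": _read_gro, "pdb": _read_pdb, "xyz": _read_xyz}[fmt]
    frames = reader(lines, str(path))
    if not frames:
        raise ParseError(f"{path}: no frames found")
    n = frames[0].n_beads
    for i, fr in enumerate(frames):
        if fr.n_beads != n:
            raise StructuralError(
                f"{path}: frame {i} has {fr.n_beads} beads, frame 0 has {n}"
            )
    # default missing times to frame indices, keeping them strictly increasing
    if len(frames) > 1:
        times = np.array([fr.time for fr in frames])
        if np.any(np.diff(times) <= 0):
            for i, fr in enumerate(frames):
                fr.time = float(i)
    return frames


def write_coordinates(
    frames: Sequence[Frame],
    path,
    format: str | None = None,
    topology: Topology | None = None,
) -> None:
    """Write frames to a text coordinate file readable by read_coordinates.

    A topology supplies species labels for atom-name fields; without one a
    generic ``CG`` label is written.  Lossless up to the format's decimal
    precision (GRO: 3 decimals in nm; PDB/XYZ: 3 decimals in A).
    """
    if len(frames) == 0:
        raise ValueError("no frames to write")
    fmt = _resolve_format(path, format)
    names = topology.species if topology is not None else None
    writer = {"gro": _write_gro, "pdb": _write_pdb, "xyz": _write_xyz}[fmt]
    with open(path, "w") as fh:
        writer(fh, frames, names)


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _read_gro(lines: list[str], src: str) -> list[Frame]:
    frames: list[Frame] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        time = None
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0]) / 1000.0  # ps -> ns
            except (IndexError, ValueError):
                time = None
        if i + 1 >= n_lines:
            raise ParseError(f"{src}: line {i + 2}: expected atom count")
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError as exc:
            raise ParseError(
                f"{src}: line {i + 2}: expected integer atom count, got "
                f"{lines[i + 1].strip()!r}"
            ) from exc
        start = i + 2
        if start + natoms >= n_lines + 1 and natoms > 0:
            raise ParseError(f"{src}: truncated frame starting at line {i + 1}")
        pos = np.empty((natoms, 3))
        for k in range(natoms):
            ln = lines[start + k]
            try:
                pos[k] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
            except (ValueError, IndexError) as exc:
                raise ParseError(
                    f"{src}: line {start + k + 1}: malformed GRO atom record"
                ) from exc
        box_line_idx = start + natoms
        if box_line_idx >= n_lines:
            raise ParseError(f"{src}: line {box_line_idx + 1}: missing box line")
        box = _parse_gro_box(lines[box_line_idx], src, box_line_idx + 1)
        frames.append(
            Frame(
                time=float(time) if time is not None else float(len(frames)),
                positions=pos * 10.0,  # nm -> A
                box=box * 10.0,
            )
        )
        i = box_line_idx + 1
    return frames


def _parse_gro_box(line: str, src: str, lineno: int) -> np.ndarray:
    try:
        vals = [float(x) for x in line.split()]
    except ValueError as exc:
        raise ParseError(f"{src}: line {lineno}: malformed box line") from exc
    if len(vals) == 3:
        return np.array(vals)
    if len(vals) == 9:
        if any(abs(v) > 1e-9 for v in vals[3:]):
            raise StructuralError(
                f"{src}: line {lineno}: triclinic box not supported (orthorhombic only)"
            )
        return np.array(vals[:3])
    raise ParseError(f"{src}: line {lineno}: box line must have 3 or 9 fields")


def _write_gro(fh, frames: Sequence[Frame], names) -> None:
    for frame in frames:
        fh.write(f"npmicroenv frame t= {frame.time * 1000.0:.5f}\n")
        fh.write(f"{frame.n_beads:5d}\n")
        pos_nm = frame.positions / 10.0
        for k in range(frame.n_beads):
            name = (names[k] if names is not None else "CG")[:5]
            resid = (k // 100000) % 100000
            fh.write(
                f"{(resid + 1) % 100000:5d}{'MOL':<5s}{name:>5s}{(k + 1) % 100000:5d}"
                f"{pos_nm[k, 0]:8.3f}{pos_nm[k, 1]:8.3f}{pos_nm[k, 2]:8.3f}\n"
            )
        b = frame.box / 10.0
        fh.write(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _read_pdb(lines: list[str], src: str) -> list[Frame]:
    box = None
    frames: list[Frame] = []
    current: list[tuple[float, float, float]] | None = None
    seen_model = False
    for lineno, ln in enumerate(lines, start=1):
        rec = ln[:6].strip()
        if rec == "CRYST1":
            try:
                box = np.array([float(ln[6:15]), float(ln[15:24]), float(ln[24:33])])
                angles = [float(ln[33:40]), float(ln[40:47]), float(ln[47:54])]
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{src}: line {lineno}: malformed CRYST1 record") from exc
            if any(abs(a - 90.0) > 1e-6 for a in angles):
                raise StructuralError(
                    f"{src}: line {lineno}: triclinic box not supported (orthorhombic only)"
                )
        elif rec == "MODEL":
            seen_model = True
            current = []
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                current = []
            try:
                current.append((float(ln[30:38]), float(ln[38:46]), float(ln[46:54])))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{src}: line {lineno}: malformed ATOM record") from exc
        elif rec == "ENDMDL":
            if current is None:
                raise ParseError(f"{src}: line {lineno}: ENDMDL without MODEL")
            frames.append(_pdb_frame(current, box, len(frames), src))
            current = None
    if current:  # single-frame file without MODEL/ENDMDL
        frames.append(_pdb_frame(current, box, len(frames), src))
    elif current is not None and not frames and seen_model:
        raise ParseError(f"{src}: MODEL with no atoms")
    return frames


def _pdb_frame(coords, box, index: int, src: str) -> Frame:
    if box is None:
        raise ParseError(f"{src}: missing CRYST1 box record")
    return Frame(time=float(index), positions=np.array(coords), box=box.copy())


def _write_pdb(fh, frames: Sequence[Frame], names) -> None:
    fh.write("TITLE     npmicroenv trajectory\n")
    b = frames[0].box
    fh.write(
        f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
    )
    for m, frame in enumerate(frames, start=1):
        if not np.allclose(frame.box, b):
            raise StructuralError("PDB output requires a constant box across frames")
        fh.write(f"MODEL     {m:4d}\n")
        for k in range(frame.n_beads):
            name = (names[k] if names is not None else "CG")[:4]
            x, y, z = frame.positions[k]
            fh.write(
                f"ATOM  {(k + 1) % 100000:5d} {name:>4s} MOL A{(k % 9999) + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
            )
        fh.write("ENDMDL\n")
    fh.write("END\n")


# ---------------------------------------------------------------------------
# XYZ (extended: comment line carries time and box)
# ---------------------------------------------------------------------------

def _read_xyz(lines: list[str], src: str) -> list[Frame]:
    frames: list[Frame] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(
                f"{src}: line {i + 1}: expected atom count, got {lines[i].strip()!r}"
            ) from exc
        if i + 1 >= n_lines:
            raise ParseError(f"{src}: line {i + 2}: missing comment line")
        time, box = _parse_xyz_comment(lines[i + 1], src, i + 2)
        start = i + 2
        if start + natoms > n_lines:
            raise ParseError(f"{src}: truncated frame starting at line {i + 1}")
        pos = np.empty((natoms, 3))
        for k in range(natoms):
            parts = lines[start + k].split()
            if len(parts) < 4:
                raise ParseError(f"{src}: line {start + k + 1}: malformed XYZ atom record")
            try:
                pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ParseError(
                    f"{src}: line {start + k + 1}: malformed XYZ atom record"
                ) from exc
        frames.append(
            Frame(
                time=time if time is not None else float(len(frames)),
                positions=pos,
                box=box,
            )
        )
        i = start + natoms
    return frames


def _parse_xyz_comment(line: str, src: str, lineno: int):
    time = None
    box = None
    if "time=" in line:
        try:
            time = float(line.split("time=")[1].split()[0])
        except (IndexError, ValueError):
            time = None
    if 'box="' in line:
        try:
            box = np.array([float(x) for x in line.split('box="')[1].split('"')[0].split()])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{src}: line {lineno}: malformed box entry") from exc
    if box is None or box.shape != (3,):
        raise ParseError(
            f'{src}: line {lineno}: XYZ comment must carry box="lx ly lz" (Angstrom)'
        )
    return time, box


def _write_xyz(fh, frames: Sequence[Frame], names) -> None:
    for frame in frames:
        fh.write(f"{frame.n_beads}\n")
        b = frame.box
        fh.write(f'time={frame.time:.6f} box="{b[0]:.3f} {b[1]:.3f} {b[2]:.3f}"\n')
        for k in range(frame.n_beads):
            name = names[k] if names is not None else "CG"
            x, y, z = frame.positions[k]
            fh.write(f"{name:<5s} {x:12.3f} {y:12.3f} {z:12.3f}\n")
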