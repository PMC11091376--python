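"""File formats for the toolkit.

Reads and writes a minimal LS-DYNA-keyword-style text dialect for finite
element meshes (``*NODE``, ``*ELEMENT_SHELL``, ``*ELEMENT_SOLID``,
``*SET_NODE_LIST`` blocks), STL/OBJ triangle surfaces, and the CSV schemas
used for landmark tables and time-history signals.

Units are millimetres for all mesh coordinates; subject characteristics are
years (age), metres (height) and kg/m^2 (BMI). Node and element ids are
1-based as in keyword files.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

logger = logging.getLogger(__name__)

__all__ = [
    "FEMesh",
    "TriSurface",
    "SubjectCharacteristics",
    "Signal",
    "MeshParseError",
    "read_mesh",
    "write_mesh",
    "read_surface",
    "write_surface",
    "read_landmark_table",
    "write_landmark_table",
    "read_signal",
    "write_signal",
]


class MeshParseError(ValueError):
    """Raised when a keyword file violates the supported dialect."""


@dataclass(frozen=True)
class SubjectCharacteristics:
    """Body characteristics driving the shape model.

    gender is coded 0 (female) / 1 (male); age in years; height in metres;
    bmi in kg/m^2.
    """

    gender: int
    age: float
    height: float
    bmi: float

    def __post_init__(self) -> None:
        if self.gender not in (0, 1):
            raise ValueError(f"gender must be 0 or 1, got {self.gender}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not 0.5 < self.height < 2.5:
            raise ValueError(f"height {self.height} m outside (0.5, 2.5)")
        if not 10 < self.bmi < 60:
            raise ValueError(f"bmi {self.bmi} kg/m^2 outside (10, 60)")

    def as_array(self) -> np.ndarray:
        return np.array(
            [float(self.gender), self.age, self.height, self.bmi], dtype=float
        )


@dataclass
class FEMesh:
    """Finite-element head mesh: nodes plus shell/solid connectivity.

    ``node_ids`` are 1-based file ids; ``shells``/``solids`` are arrays with
    columns (element id, part id, node ids...), padded with the last node id
    repeated for triangles (keyword convention). ``landmark_set`` is an
    ordered list of node ids designated as morphing landmarks.
    """

    node_ids: np.ndarray
    node_coords: np.ndarray
    shells: np.ndarray = field(default_factory=lambda: np.empty((0, 6), dtype=np.int64))
    solids: np.ndarray = field(default_factory=lambda: np.empty((0, 10), dtype=np.int64))
    landmark_set: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    part_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.node_coords = np.asarray(self.node_coords, dtype=float).reshape(-1, 3)
        self.shells = np.asarray(self.shells, dtype=np.int64).reshape(-1, 6)
        self.solids = np.asarray(self.solids, dtype=np.int64).reshape(-1, 10)
        self.landmark_set = np.asarray(self.landmark_set, dtype=np.int64)
        self.validate()
        # id -> row lookup for node coordinates
        self._index = {int(nid): i for i, nid in enumerate(self.node_ids)}

    def validate(self) -> None:
        ids, counts = np.unique(self.node_ids, return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][0]
            raise MeshParseError(f"duplicate node id {int(dup)}")
        if len(self.node_ids) != len(self.node_coords):
            raise MeshParseError("node id/coordinate count mismatch")
        known = set(int(i) for i in self.node_ids)
        for name, table, width in (("shell", self.shells, 4), ("solid", self.solids, 8)):
            for row in table:
                for nid in row[2 : 2 + width]:
                    if int(nid) not in known:
                        raise MeshParseError(
                            f"{name} element {int(row[0])} references missing node {int(nid)}"
                        )
        if len(np.unique(self.landmark_set)) != len(self.landmark_set):
            raise MeshParseError("landmark set contains duplicate node ids")
        for nid in self.landmark_set:
            if int(nid) not in known:
                raise MeshParseError(f"landmark references missing node {int(nid)}")

    # -- convenience ------------------------------------------------------
    def node_index(self, node_ids: Sequence[int] | np.ndarray) -> np.ndarray:
        return np.array([self._index[int(n)] for n in np.asarray(node_ids).ravel()])

    def coords_of(self, node_ids: Sequence[int] | np.ndarray) -> np.ndarray:
        return self.node_coords[self.node_index(node_ids)]

    @property
    def landmark_coords(self) -> np.ndarray:
        return self.coords_of(self.landmark_set)

    def shell_corner_counts(self) -> np.ndarray:
        """4 for quads, 3 for triangles (last node id repeated)."""
        return np.where(self.shells[:, 4] == self.shells[:, 5], 3, 4)

    def solid_corner_counts(self) -> np.ndarray:
        """8 for hexahedra, 4 for tetrahedra (nodes 4..8 repeated)."""
        degen = (self.solids[:, 5:10] == self.solids[:, 5][:, None]).all(axis=1)
        return np.where(degen, 4, 8)

    def with_coords(self, coords: np.ndarray) -> "FEMesh":
        """Same connectivity, new node coordinates (morphing)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.node_coords.shape:
            raise ValueError("coordinate array shape mismatch")
        return FEMesh(
            node_ids=self.node_ids.copy(),
            node_coords=coords.copy(),
            shells=self.shells.copy(),
            solids=self.solids.copy(),
            landmark_set=self.landmark_set.copy(),
            part_labels=dict(self.part_labels),
        )


@dataclass
class TriSurface:
    """Triangulated surface: vertices (mm) and 0-based triangle indices."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle index out of range")

    def triangle_corners(self) -> np.ndarray:
        """(n_tri, 3, 3) corner coordinate array."""
        return self.vertices[self.triangles]


@dataclass
class Signal:
    """Time–value series with a strictly increasing time axis (seconds)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        if len(self.times) < 2:
            raise ValueError("signal needs at least 2 samples")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("time axis must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# keyword-dialect mesh I/O
# ---------------------------------------------------------------------------

_KNOWN_KEYWORDS = ("*NODE", "*ELEMENT_SHELL", "*ELEMENT_SOLID", "*SET_NODE_LIST",
                   "*PART", "*KEYWORD", "*END")


def read_mesh(path: str | Path, dialect: str = "keyword") -> FEMesh:
    """Read an FE mesh from a keyword-dialect text file.

    Supported blocks: ``*NODE`` (id x y z), ``*ELEMENT_SHELL`` (id part n1..n4,
    triangles repeat the last node), ``*ELEMENT_SOLID`` (id part n1..n8,
    tetrahedra repeat node 4), ``*SET_NODE_LIST`` (landmark node ids, order
    preserved), ``*PART`` (id name). Unknown blocks and ``$`` comment lines
    are skipped with a warning. All fields are whitespace- or
    comma-separated.
    """
    if dialect not in ("keyword", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    node_ids: list[int] = []
    coords: list[list[float]] = []
    shells: list[list[int]] = []
    solids: list[list[int]] = []
    landmarks: list[int] = []
    part_labels: dict[int, str] = {}
    block = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$"):
                continue
            if line.startswith("*"):
                key = line.split()[0].upper()
                if key not in _KNOWN_KEYWORDS:
                    logger.warning("%s:%d: skipping unknown block %s", path, lineno, key)
                    block = None
                elif key in ("*KEYWORD", "*END"):
                    block = None
                else:
                    block = key
                continue
            if block is None:
                continue
            fields = line.replace(",", " ").split()
            try:
                if block == "*NODE":
                    node_ids.append(int(fields[0]))
                    coords.append([float(v) for v in fields[1:4]])
                elif block == "*ELEMENT_SHELL":
                    vals = [int(v) for v in fields]
                    if len(vals) == 5:  # triangle: pad with last node
                        vals.append(vals[-1])
                    if len(vals) != 6:
                        raise ValueError("shell rows need 3 or 4 node ids")
                    shells.append(vals)
                elif block == "*ELEMENT_SOLID":
                    vals = [int(v) for v in fields]
                    if len(vals) == 6:  # tetra: pad to 8 corners
                        vals += [vals[-1]] * 4
                    if len(vals) != 10:
                        raise ValueError("solid rows need 4 or 8 node ids")
                    solids.append(vals)
                elif block == "*SET_NODE_LIST":
                    landmarks.extend(int(v) for v in fields)
                elif block == "*PART":
                    part_labels[int(fields[0])] = " ".join(fields[1:]) or str(fields[0])
            except (ValueError, IndexError) as exc:
                raise MeshParseError(f"{path}:{lineno}: {exc}") from exc
    try:
        return FEMesh(
            node_ids=np.array(node_ids, dtype=np.int64),
            node_coords=np.array(coords, dtype=float).reshape(-1, 3),
            shells=np.array(shells, dtype=np.int64).reshape(-1, 6),
            solids=np.array(solids, dtype=np.int64).reshape(-1, 10),
            landmark_set=np.array(landmarks, dtype=np.int64),
            part_labels=part_labels,
        )
    except MeshParseError as exc:
        raise MeshParseError(f"{path}: {exc}") from exc


def write_mesh(mesh: FEMesh, path: str | Path, dialect: str = "keyword") -> None:
    """Write a mesh in the keyword dialect, re-readable by :func:`read_mesh`.

    Coordinates are printed with 12 significant digits so a round trip is
    exact to well below 1e-6 mm.
    """
    if dialect not in ("keyword", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    mesh.validate()
    lines = ["*KEYWORD"]
    for pid, name in sorted(mesh.part_labels.items()):
        lines.append("*PART")
        lines.append(f"{pid} {name}")
    lines.append("*NODE")
    for nid, (x, y, z) in zip(mesh.node_ids, mesh.node_coords):
        lines.append(f"{int(nid)} {x:.12g} {y:.12g} {z:.12g}")
    if len(mesh.shells):
        lines.append("*ELEMENT_SHELL")
        for row in mesh.shells:
            lines.append(" ".join(str(int(v)) for v in row))
    if len(mesh.solids):
        lines.append("*ELEMENT_SOLID")
        for row in mesh.solids:
            lines.append(" ".join(str(int(v)) for v in row))
    if len(mesh.landmark_set):
        lines.append("*SET_NODE_LIST")
        for nid in mesh.landmark_set:
            lines.append(str(int(nid)))
    lines.append("*END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# triangle surfaces (STL / OBJ via trimesh)
# ---------------------------------------------------------------------------

def read_surface(path: str | Path, allow_degenerate: bool = False) -> TriSurface:
    """Load an STL or OBJ triangle surface."""
    tm = trimesh.load(str(path), force="mesh", process=False)
    surf = TriSurface(np.asarray(tm.vertices, dtype=float),
                      np.asarray(tm.faces, dtype=np.int64))
    if not allow_degenerate:
        corners = surf.triangle_corners()
        areas = 0.5 * np.linalg.norm(
            np.cross(corners[:, 1] - corners[:, 0], corners[:, 2] - corners[:, 0]),
            axis=1,
        )
        if (areas <= 0).any():
            raise ValueError(
                f"surface contains {(areas <= 0).sum()} zero-area triangles"
            )
    return surf


def write_surface(surface: TriSurface, path: str | Path) -> None:
    tm = trimesh.Trimesh(vertices=surface.vertices, faces=surface.triangles,
                         process=False)
    tm.export(str(path))


# ---------------------------------------------------------------------------
# landmark tables
# ---------------------------------------------------------------------------

def read_landmark_table(
    path: str | Path,
) -> list[tuple[str, SubjectCharacteristics, np.ndarray]]:
    """Read a per-subject landmark CSV.

    Schema: ``subject_id, gender, age, height, bmi, x1, y1, z1, x2, ...``.
    Every subject must carry the same landmark count; landmarks are ordered
    by column index.
    """
    out: list[tuple[str, SubjectCharacteristics, np.ndarray]] = []
    m_expected: int | None = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty file")
        for row in reader:
            if not row:
                continue
            sid = row[0]
            try:
                chars = SubjectCharacteristics(
                    gender=int(float(row[1])), age=float(row[2]),
                    height=float(row[3]), bmi=float(row[4]),
                )
                flat = np.array([float(v) for v in row[5:]], dtype=float)
            except ValueError as exc:
                raise ValueError(f"{path}: subject {sid}: {exc}") from exc
            if flat.size % 3 != 0:
                raise ValueError(
                    f"{path}: subject {sid}: {flat.size} coordinates not divisible by 3"
                )
            m = flat.size // 3
            if m_expected is None:
                m_expected = m
            elif m != m_expected:
                raise ValueError(
                    f"{path}: ragged landmark counts ({m} vs {m_expected}) at subject {sid}"
                )
            out.append((sid, chars, flat.reshape(m, 3)))
    return out


def write_landmark_table(
    subjects: Sequence[tuple[str, SubjectCharacteristics, np.ndarray]],
    path: str | Path,
) -> None:
    m = np.asarray(subjects[0][2]).shape[0]
    header = ["subject_id", "gender", "age", "height", "bmi"]
    for i in range(1, m + 1):
        header += [f"x{i}", f"y{i}", f"z{i}"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for sid, chars, lms in subjects:
            lms = np.asarray(lms, dtype=float)
            row = [sid, chars.gender, repr(chars.age), repr(chars.height),
                   repr(chars.bmi)]
            row += [repr(float(v)) for v in lms.ravel()]
            w.writerow(row)


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def read_signal(path: str | Path) -> Signal:
    """Read a two-column ``time,value`` CSV (header optional)."""
    times: list[float] = []
    values: list[float] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                t, v = float(row[0]), float(row[1])
            except ValueError:
                if not times:  # tolerate a single header line
                    continue
                raise
            times.append(t)
            values.append(v)
    return Signal(np.array(times), np.array(values))


def write_signal(signal: Signal, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "value"])
        for t, v in zip(signal.times, signal.values):
            w.writerow([repr(float(t)), repr(float(v))])
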