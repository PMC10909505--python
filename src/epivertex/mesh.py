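"""Polygonal tissue mesh: construction, geometry, validation and snapshot I/O.

The apical surface of an epithelium is represented as a shared-vertex
tessellation: a flat array of 2D vertex positions plus, per cell, an ordered
counter-clockwise loop of vertex indices.  Interior junctions are
tri-junctions (degree-3 vertices); every interior edge is shared by exactly
two cells and traversed in opposite directions by them.  The tissue boundary
is free: boundary edges belong to a single cell and boundary vertices may
have degree 2 or 3.

Cell and vertex identifiers increase monotonically and are never reused
after removal (T2) or division, so lineages and event logs stay unambiguous.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "MeshError",
    "OrientationError",
    "SnapshotError",
    "CellGeometry",
    "TissueMesh",
    "build_hexagonal_lattice",
    "cell_geometry",
    "signed_area",
    "polygon_perimeter",
    "polygon_centroid",
    "edge_cells",
    "directed_edge_map",
    "validate_mesh",
    "write_snapshot",
    "read_snapshot",
    "cell_polygons",
    "hexagon_side_for_area",
]

#: area of a regular hexagon of unit side
HEX_UNIT_AREA = 1.5 * math.sqrt(3.0)


class MeshError(Exception):
    """The mesh violates a structural invariant."""


class OrientationError(MeshError):
    """A cell loop is not counter-clockwise."""


class SnapshotError(MeshError):
    """A snapshot file is malformed."""


@dataclass(frozen=True)
class CellGeometry:
    """Scalar geometry of one cell: area A, perimeter L, side count n, centroid."""

    area: float
    perimeter: float
    neighbour_count: int
    centroid: tuple[float, float]


class TissueMesh:
    """Shared-vertex tessellation of a planar tissue.

    Parameters
    ----------
    vertices : (n, 2) array-like
        Vertex positions.  Row index is the vertex id.  Rows may become
        orphaned (unreferenced) after topological surgery; they are kept so
        that vertex ids are never reused.
    cells : mapping int -> sequence of int
        Ordered CCW vertex loops keyed by stable cell id.
    time : float
        Simulation time attached to this configuration.
    """

    def __init__(self, vertices, cells, time: float = 0.0, next_cell_id: int | None = None):
        self.vertices = np.array(vertices, dtype=float).reshape(-1, 2)
        self.cells: dict[int, list[int]] = {int(k): [int(v) for v in loop] for k, loop in cells.items()}
        self.time = float(time)
        auto = (max(self.cells) + 1) if self.cells else 0
        self._next_cell_id = auto if next_cell_id is None else max(int(next_cell_id), auto)

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vertices(self) -> int:
        """Number of vertex rows (including orphaned ones)."""
        return self.vertices.shape[0]

    def used_vertices(self) -> np.ndarray:
        """Sorted ids of vertices referenced by at least one cell."""
        if not self.cells:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate([np.asarray(l) for l in self.cells.values()]))

    def add_vertex(self, xy) -> int:
        self.vertices = np.vstack([self.vertices, np.asarray(xy, dtype=float).reshape(1, 2)])
        return self.vertices.shape[0] - 1

    def new_cell_id(self) -> int:
        cid = self._next_cell_id
        self._next_cell_id += 1
        return cid

    def polygon(self, cell_id: int) -> np.ndarray:
        """(n, 2) coordinates of the cell loop."""
        try:
            loop = self.cells[cell_id]
        except KeyError:
            raise LookupError(f"unknown cell id {cell_id!r}") from None
        return self.vertices[np.asarray(loop, dtype=int)]

    def copy(self) -> "TissueMesh":
        return TissueMesh(self.vertices.copy(), {k: list(v) for k, v in self.cells.items()},
                          time=self.time, next_cell_id=self._next_cell_id)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TissueMesh(n_cells={self.n_cells}, n_vertices={self.n_vertices}, time={self.time:g})"


# -- scalar polygon helpers ----------------------------------------------

def signed_area(coords: np.ndarray) -> float:
    """Shoelace signed area of an ordered loop (positive for CCW)."""
    x, y = coords[:, 0], coords[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def polygon_perimeter(coords: np.ndarray) -> float:
    return float(np.linalg.norm(np.roll(coords, -1, axis=0) - coords, axis=1).sum())


def polygon_centroid(coords: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon (falls back to vertex mean if degenerate)."""
    x, y = coords[:, 0], coords[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-300:
        return coords.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def cell_geometry(mesh: TissueMesh, cell_id: int) -> CellGeometry:
    """Area (shoelace), perimeter and side count of one cell.

    Raises
    ------
    LookupError
        If ``cell_id`` is not in the mesh.
    OrientationError
        If the loop is clockwise (non-positive signed area).  Constructors
        normalise loops to CCW, so a CW loop here indicates a surgery bug and
        is never silently fixed.
    """
    coords = mesh.polygon(cell_id)
    a = signed_area(coords)
    if a <= 0.0:
        raise OrientationError(f"cell {cell_id} has non-CCW loop (signed area {a:g})")
    c = polygon_centroid(coords)
    return CellGeometry(area=a, perimeter=polygon_perimeter(coords),
                        neighbour_count=len(coords), centroid=(float(c[0]), float(c[1])))


# -- lattice construction -------------------------------------------------

def hexagon_side_for_area(area: float) -> float:
    """Side length of a regular hexagon with the given area."""
    return math.sqrt(area / HEX_UNIT_AREA)


def build_hexagonal_lattice(n_cells: int, side: float) -> TissueMesh:
    """Build a connected patch of ``n_cells`` regular hexagons of edge ``side``.

    Cells are laid out row by row (the last row truncated), pointy-top
    orientation, shared vertices deduplicated exactly via the integer
    half-lattice the hexagon corners live on.  All loops are CCW.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    if not side > 0.0:
        raise ValueError(f"side must be > 0, got {side}")

    s = float(side)
    rt3h = math.sqrt(3.0) / 2.0 * s
    # corner offsets relative to a hexagon centre, CCW starting from the top
    offsets = [(0.0, s), (-rt3h, 0.5 * s), (-rt3h, -0.5 * s),
               (0.0, -s), (rt3h, -0.5 * s), (rt3h, 0.5 * s)]
    # corners lie on the lattice x = ix*(sqrt3/2)s, y = iy*(s/2)
    ioffsets = [(0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1), (1, 1)]

    ncols = max(1, math.ceil(math.sqrt(n_cells)))
    index_of: dict[tuple[int, int], int] = {}
    verts: list[tuple[float, float]] = []
    cells: dict[int, list[int]] = {}

    made = 0
    row = 0
    while made < n_cells:
        for col in range(ncols):
            if made >= n_cells:
                break
            # integer centre coordinates on the same half-lattice
            icx = 2 * col + (row % 2)
            icy = 3 * row
            cx = icx * rt3h
            cy = icy * (0.5 * s)
            loop = []
            for (dx, dy), (idx, idy) in zip(offsets, ioffsets):
                key = (icx + idx, icy + idy)
                vid = index_of.get(key)
                if vid is None:
                    vid = len(verts)
                    verts.append((cx + dx, cy + dy))
                    index_of[key] = vid
                loop.append(vid)
            cells[made] = loop
            made += 1
        row += 1

    return TissueMesh(np.asarray(verts, dtype=float), cells, time=0.0)


# -- adjacency helpers ----------------------------------------------------

def edge_cells(mesh: TissueMesh) -> dict[tuple[int, int], list[int]]:
    """Map unordered edge (a < b) -> list of incident cell ids (1 or 2)."""
    out: dict[tuple[int, int], list[int]] = {}
    for cid, loop in mesh.cells.items():
        n = len(loop)
        for i in range(n):
            a, b = loop[i], loop[(i + 1) % n]
            key = (a, b) if a < b else (b, a)
            out.setdefault(key, []).append(cid)
    return out


def directed_edge_map(mesh: TissueMesh) -> dict[tuple[int, int], int]:
    """Map directed edge (a, b) -> the cell whose loop traverses a -> b."""
    out: dict[tuple[int, int], int] = {}
    for cid, loop in mesh.cells.items():
        n = len(loop)
        for i in range(n):
            out[(loop[i], loop[(i + 1) % n])] = cid
    return out


def vertex_cells(mesh: TissueMesh) -> dict[int, list[int]]:
    out: dict[int, list[int]] = {}
    for cid, loop in mesh.cells.items():
        for v in loop:
            out.setdefault(v, []).append(cid)
    return out


def validate_mesh(mesh: TissueMesh, check_simple: bool = True) -> None:
    """Check all structural invariants; raise :class:`MeshError` on failure.

    Checks: valid vertex indices, loops of length >= 3 without repeats,
    positive (CCW) shoelace area, simple polygons (via shapely), each edge
    shared by at most two cells with opposite traversal directions, and
    tri-junction degree: a vertex incident to three cells has exactly three
    edges, and no vertex is incident to more than three cells.
    """
    nv = mesh.n_vertices
    for cid, loop in mesh.cells.items():
        if len(loop) < 3:
            raise MeshError(f"cell {cid} has fewer than 3 vertices")
        if len(set(loop)) != len(loop):
            raise MeshError(f"cell {cid} repeats a vertex in its loop")
        for v in loop:
            if not (0 <= v < nv):
                raise MeshError(f"cell {cid} references invalid vertex {v}")
        coords = mesh.vertices[np.asarray(loop)]
        if signed_area(coords) <= 0.0:
            raise MeshError(f"cell {cid} is not CCW")
        if check_simple and not Polygon(coords).is_valid:
            raise MeshError(f"cell {cid} is not a simple polygon")

    directed: set[tuple[int, int]] = set()
    for cid, loop in mesh.cells.items():
        n = len(loop)
        for i in range(n):
            e = (loop[i], loop[(i + 1) % n])
            if e in directed:
                raise MeshError(f"directed edge {e} traversed twice (orientation clash)")
            directed.add(e)
    for key, cids in edge_cells(mesh).items():
        if len(cids) > 2:
            raise MeshError(f"edge {key} shared by more than two cells: {cids}")

    degree: dict[int, set[int]] = {}
    for a, b in directed:
        degree.setdefault(a, set()).add(b)
        degree.setdefault(b, set()).add(a)
    for v, cids in vertex_cells(mesh).items():
        if len(cids) > 3:
            raise MeshError(f"vertex {v} belongs to {len(cids)} cells")
        if len(cids) == 3 and len(degree[v]) != 3:
            raise MeshError(f"interior vertex {v} has degree {len(degree[v])} != 3")


# -- snapshot I/O ---------------------------------------------------------

def write_snapshot(mesh: TissueMesh, states, path) -> None:
    """Write mesh + per-cell states to a JSON snapshot.

    Schema: ``{"time", "vertices": [[x, y], ...], "cells": [{"id", "loop",
    "birth_time", "tc", "parent_id"}, ...], "next_cell_id"}``.  Floats are
    serialised with shortest round-trip repr, so coordinates survive
    bit-for-bit.
    """
    cells = []
    for cid, loop in mesh.cells.items():
        st = states.get(cid) if states else None
        cells.append({
            "id": int(cid),
            "loop": [int(v) for v in loop],
            "birth_time": None if st is None else float(st.birth_time),
            "tc": None if st is None else float(st.tc),
            "parent_id": None if st is None or st.parent_id is None else int(st.parent_id),
        })
    data = {
        "time": mesh.time,
        "vertices": [[float(x), float(y)] for x, y in mesh.vertices],
        "cells": cells,
        "next_cell_id": mesh._next_cell_id,
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def read_snapshot(path):
    """Read a JSON snapshot; returns ``(mesh, states)``.

    Raises :class:`SnapshotError` naming the first missing/invalid field.
    """
    from .cellcycle import CellState  # local import: cellcycle imports mesh

    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SnapshotError(f"not valid JSON: {exc}") from exc
    for field in ("time", "vertices", "cells"):
        if field not in data:
            raise SnapshotError(f"snapshot missing field {field!r}")
    cells = {}
    states = {}
    for i, rec in enumerate(data["cells"]):
        for field in ("id", "loop"):
            if field not in rec:
                raise SnapshotError(f"cells[{i}] missing field {field!r}")
        cid = int(rec["id"])
        cells[cid] = [int(v) for v in rec["loop"]]
        if rec.get("birth_time") is not None:
            states[cid] = CellState(cell_id=cid, birth_time=rec["birth_time"],
                                    tc=rec["tc"], parent_id=rec.get("parent_id"))
    mesh = TissueMesh(np.asarray(data["vertices"], dtype=float), cells,
                      time=data["time"], next_cell_id=data.get("next_cell_id"))
    return mesh, states


def cell_polygons(mesh: TissueMesh) -> dict[int, Polygon]:
    """Export cells as shapely polygons (plotting / GIS-style interchange)."""
    return {cid: Polygon(mesh.polygon(cid)) for cid in mesh.cells}
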