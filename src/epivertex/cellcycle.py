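"""Stochastic cell cycle: intrinsic cycle lengths, target-area schedule,
cytokinesis gating and division surgery.

Each cell draws an intrinsic cycle length at birth,

    t_c ~ eps * T_c + Exp(mean = (1 - eps) * T_c),

a shifted exponential with mean <t_c> = T_c and support [eps*T_c, inf).
``eps`` weights the deterministic versus stochastic parts of the cycle
(eps = 1 is a synchronous-division limit, eps = 0 a memoryless one).

While a cell ages its preferred (target) area follows

    A0(age) = 1                      for age <  t_c / 2,
    A0(age) = min(2 age / t_c, A_f)  for age >= t_c / 2,

i.e. constant through the first half of the cycle, then linear growth to 2
at age t_c.  The clamp at A_f ("maximum target area of a mitotic cell")
keeps the elastic driving bounded when high friction delays division past
t_c; without it the schedule would grow without bound while the cell waits.

Cytokinesis requires age >= t_c AND (optionally) apical area >= A_c.
Disabling the area gate reproduces the A_c = 0 model variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from shapely.geometry import Polygon

from . import mesh as meshmod
from .mesh import TissueMesh, polygon_centroid, signed_area

__all__ = ["CellCycleParams", "CellState", "sample_tc", "target_area",
           "division_ready", "divide_cell"]


@dataclass(frozen=True)
class CellCycleParams:
    Tc: float = 388.0          #: mean intrinsic cycle duration (time)
    epsilon: float = 0.8       #: deterministic fraction of the cycle, in [0, 1]
    A_f: float = 2.0           #: maximum target area of a mitotic cell (length^2)
    A_c: float = 1.56          #: critical division area, default 0.78 * A_f (length^2)
    with_area_gate: bool = True  #: False reproduces the A_c = 0 ablation

    def __post_init__(self):
        if not self.Tc > 0:
            raise ValueError("Tc must be > 0")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        if not self.A_f > 0:
            raise ValueError("A_f must be > 0")
        if not 0.0 <= self.A_c <= self.A_f:
            raise ValueError("A_c must be in [0, A_f]")

    def without_gate(self) -> "CellCycleParams":
        return replace(self, with_area_gate=False)


@dataclass
class CellState:
    """Per-cell record driving the cycle: birth time, sampled t_c, lineage."""

    cell_id: int
    birth_time: float
    tc: float
    parent_id: int | None = None

    def age(self, now: float) -> float:
        return now - self.birth_time


def sample_tc(params: CellCycleParams, rng: np.random.Generator, size=None):
    """Draw intrinsic cycle length(s): eps*Tc + Exp(mean (1-eps)*Tc)."""
    scale = (1.0 - params.epsilon) * params.Tc
    return params.epsilon * params.Tc + rng.exponential(scale, size=size)


def target_area(age: float, tc: float, A_f: float = 2.0) -> float:
    """Target-area schedule A0(age) for a cell with intrinsic length tc."""
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    if not tc > 0:
        raise ValueError("tc must be > 0")
    if age < 0.5 * tc:
        return 1.0
    return min(2.0 * age / tc, A_f)


def division_ready(state: CellState, now: float, area: float,
                   params: CellCycleParams) -> bool:
    """True iff age >= t_c and (area gate off or area >= A_c)."""
    if state.age(now) < state.tc:
        return False
    return (not params.with_area_gate) or area >= params.A_c


# -- division surgery -----------------------------------------------------

def _line_polygon_crossings(coords: np.ndarray, point: np.ndarray, direction: np.ndarray,
                            margin: float, min_edge: float):
    """Indices and points where the infinite line crosses polygon edges.

    Returns a list of ``(edge_index, s, xy)`` with ``s`` the parameter along
    the edge, only accepting crossings at least a fraction ``margin`` *and*
    an absolute distance ``min_edge`` away from either endpoint (so surgery
    never creates near-degenerate edges).  ``None`` signals a crossing too
    close to a vertex or a non-generic geometry: retry with a different
    direction.
    """
    n = len(coords)
    nrm = np.array([-direction[1], direction[0]])  # normal of the split line
    d = (coords - point) @ nrm                      # signed distance of vertices
    hits = []
    for i in range(n):
        di, dj = d[i], d[(i + 1) % n]
        if di == 0.0 or dj == 0.0:
            return None           # line through a vertex: non-generic
        if (di > 0) == (dj > 0):
            continue
        s = di / (di - dj)
        seg = coords[(i + 1) % n] - coords[i]
        seg_len = float(np.hypot(*seg))
        lo = max(margin, min_edge / seg_len if seg_len > 0 else 1.0)
        if not (lo < s < 1.0 - lo):
            return None           # crossing too close to an endpoint
        p = coords[i] + s * seg
        hits.append((i, s, p))
    return hits


def divide_cell(mesh: TissueMesh, state: CellState, now: float,
                params: CellCycleParams, rng: np.random.Generator,
                log=None, max_attempts: int = 12, margin: float = 0.08,
                min_edge: float = 0.0):
    """Split a cell through its centroid along a random direction.

    One new vertex is inserted on each of the two crossed edges (and into
    the neighbouring cell's loop, preserving tri-junctions).  Daughters get
    fresh independent t_c draws, birth_time = now, the parent's id as
    lineage pointer, and a target-area schedule restarted at A0 = 1.

    Returns ``(mesh, (state_a, state_b))`` on success (the mesh is modified
    in place) or ``None`` if the split must be deferred (triangle parent, or
    no valid split line found after bounded retries).  On success a
    "division" event (with parent area and age) is appended to ``log`` when
    one is given.
    """
    cid = state.cell_id
    loop = mesh.cells[cid]
    if len(loop) < 4:
        return None     # triangle: defer one step
    coords = mesh.vertices[np.asarray(loop)]
    parent_area = signed_area(coords)
    centroid = polygon_centroid(coords)

    hits = None
    for _ in range(max_attempts):
        theta = rng.uniform(0.0, math.pi)
        direction = np.array([math.cos(theta), math.sin(theta)])
        cand = _line_polygon_crossings(coords, centroid, direction, margin, min_edge)
        if cand is not None and len(cand) == 2 and cand[0][0] != cand[1][0]:
            hits = cand
            break
    if hits is None:
        return None

    dmap = meshmod.directed_edge_map(mesh)
    n = len(loop)
    new_ids = []
    # insert higher edge index first so the lower index stays valid
    for ei, s, p in sorted(hits, key=lambda h: -h[0]):
        u, v = loop[ei], loop[(ei + 1) % n]
        nv = mesh.add_vertex(p)
        new_ids.append((ei, nv))
        loop.insert(ei + 1, nv)
        n += 1
        neighbour = dmap.get((v, u))
        if neighbour is not None:
            nloop = mesh.cells[neighbour]
            j = next(k for k in range(len(nloop))
                     if nloop[k] == v and nloop[(k + 1) % len(nloop)] == u)
            nloop.insert(j + 1, nv)

    # positions of the two new vertices in the (now longer) parent loop
    p1, p2 = sorted(loop.index(nv) for _, nv in new_ids)
    loop_a = loop[p1:p2 + 1]                 # p1 .. p2
    loop_b = loop[p2:] + loop[:p1 + 1]       # p2 .. wrap .. p1
    for lp in (loop_a, loop_b):
        if len(lp) < 3 or signed_area(mesh.vertices[np.asarray(lp)]) <= 0 \
                or not Polygon(mesh.vertices[np.asarray(lp)]).is_valid:
            # undo is awkward; in practice the margin rule prevents this,
            # treat as a failed attempt and defer
            return None

    del mesh.cells[cid]
    ida = mesh.new_cell_id()
    idb = mesh.new_cell_id()
    mesh.cells[ida] = loop_a
    mesh.cells[idb] = loop_b
    state_a = CellState(cell_id=ida, birth_time=now, tc=float(sample_tc(params, rng)),
                        parent_id=cid)
    state_b = CellState(cell_id=idb, birth_time=now, tc=float(sample_tc(params, rng)),
                        parent_id=cid)
    if log is not None:
        log.append(now, "division", (cid, ida, idb),
                   parent_area=parent_area, parent_age=now - state.birth_time)
    return mesh, (state_a, state_b)
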