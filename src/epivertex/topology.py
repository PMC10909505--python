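"""Topological transitions keeping the tessellation valid while it deforms.

T1 (neighbour exchange): a short interior edge is rotated 90 degrees about
its midpoint and rescaled to ``l_new``; the two cells that shared the edge
lose a side each and the two flanking cells gain one.  Only interior edges
whose endpoints are both full tri-junctions (three incident cells) swap;
edges touching the free boundary are skipped.

T2 (extrusion / apoptosis): a three-sided cell whose area has fallen below
``A_T2`` collapses to a single vertex at its centroid; each neighbour loses
one side.  A boundary triangle with fewer than two interior sides is peeled
off (deleted) instead.

Thresholds are numerical-regularisation knobs, not biophysical parameters:
defaults are ``l_T1 = 0.05`` and ``l_new = 0.06`` in units where the
initial cell area is 1, and ``A_T2 = 0.02``.  Qualitative simulation
results should be (and are, in tests) insensitive to their exact values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import (MeshError, TissueMesh, edge_cells, polygon_centroid,
                   signed_area, vertex_cells)

__all__ = ["TopologyParams", "EventLog", "apply_T1", "apply_T2", "sweep_topology",
           "untangle_collapsed_edges"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TopologyParams:
    l_T1: float = 0.05   #: edge length below which a T1 swap triggers
    l_new: float = 0.06  #: length of the re-formed edge after a T1
    A_T2: float = 0.02   #: area below which a 3-sided cell is removed

    def __post_init__(self):
        if not (self.l_T1 > 0 and self.l_new > 0 and self.A_T2 > 0):
            raise ValueError("all topology thresholds must be > 0")
        if not self.l_new > self.l_T1:
            raise ValueError("l_new must exceed l_T1 (else the swap immediately re-triggers)")


@dataclass
class EventRecord:
    time: float
    kind: str            # "division" | "T1" | "T2"
    cell_ids: tuple[int, ...]
    details: dict = field(default_factory=dict)


class EventLog:
    """Time-ordered record of divisions, T1 and T2 events."""

    KINDS = ("division", "T1", "T2")

    def __init__(self):
        self.records: list[EventRecord] = []

    def append(self, time: float, kind: str, cell_ids, **details) -> None:
        if kind not in self.KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        if self.records and time < self.records[-1].time - 1e-12:
            raise ValueError("event times must be non-decreasing")
        self.records.append(EventRecord(float(time), kind, tuple(int(c) for c in cell_ids), details))

    def count(self, kind: str) -> int:
        return sum(1 for r in self.records if r.kind == kind)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"time": r.time, "kind": r.kind,
                 "cell_ids": ";".join(str(c) for c in r.cell_ids),
                 "details": ";".join(f"{k}={v}" for k, v in r.details.items())}
                for r in self.records]
        return pd.DataFrame(rows, columns=["time", "kind", "cell_ids", "details"])

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def divisions(self) -> pd.DataFrame:
        """Division events as a table: time, parent, daughters, parent age/area."""
        rows = []
        for r in self.records:
            if r.kind != "division":
                continue
            parent, da, db = r.cell_ids
            rows.append({"time": r.time, "parent": parent, "daughter_a": da,
                         "daughter_b": db, **r.details})
        return pd.DataFrame(rows)


# -- T1 -------------------------------------------------------------------

def _insert_adjacent(flank_loop: list[int], old: int, new: int, keeper_loop: list[int]) -> None:
    """Insert ``new`` next to ``old`` in a flank loop after a T1.

    The correct side is fixed by the cell that keeps the *other* endpoint:
    if that cell's loop traverses (old, p) where p is the flank's
    predecessor of ``old``, the new vertex goes between p and old, else
    after old.
    """
    i = flank_loop.index(old)
    p = flank_loop[i - 1]
    n = len(keeper_loop)
    keeper_pairs = {(keeper_loop[k], keeper_loop[(k + 1) % n]) for k in range(n)}
    if (old, p) in keeper_pairs:
        flank_loop.insert(i, new)
    else:
        flank_loop.insert(i + 1, new)


def _local_energy(mesh: TissueMesh, cids, targets, mech) -> float:
    """Vertex-model energy restricted to a set of cells (each edge once)."""
    e = 0.0
    edges: set[tuple[int, int]] = set()
    for cid in cids:
        loop = mesh.cells[cid]
        coords = mesh.vertices[np.asarray(loop)]
        area = signed_area(coords)
        seg = np.roll(coords, -1, axis=0) - coords
        per = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
        e += 0.5 * mech.K * (area - targets[cid]) ** 2 + 0.5 * mech.Gamma * per ** 2
        n = len(loop)
        for i in range(n):
            u, v = loop[i], loop[(i + 1) % n]
            edges.add((u, v) if u < v else (v, u))
    for u, v in edges:
        e += mech.Lambda * float(np.hypot(*(mesh.vertices[v] - mesh.vertices[u])))
    return e


def apply_T1(mesh: TissueMesh, edge, params: TopologyParams,
             log: EventLog | None = None, now: float | None = None,
             targets=None, mech=None) -> bool:
    """Swap a short interior edge; returns False (skip) if ineligible.

    Eligible edges are interior (two incident cells) with both endpoints
    incident to exactly three cells.  Boundary and degenerate junctions are
    skipped with a debug log entry.

    When ``targets`` (per-cell A0 mapping) and ``mech``
    (:class:`~epivertex.mechanics.MechanicalParams`) are given, the swap is
    additionally *energy gated*: it is rolled back and reported as skipped
    if it would raise the local energy of the four incident cells.  Under
    overdamped relaxational dynamics an energy-raising swap is immediately
    undone by the flow, producing unphysical swap/unswap churn at
    tension-collapsed junctions; gating leaves such junctions as
    (near-)fourfold vertices until the neighbourhood changes.
    """
    a, b = edge
    vc = vertex_cells(mesh)
    cells_a = set(vc.get(a, ()))
    cells_b = set(vc.get(b, ()))
    sharers = cells_a & cells_b
    if len(sharers) != 2 or len(cells_a) != 3 or len(cells_b) != 3:
        logger.debug("T1 skipped on edge (%s, %s): boundary or non tri-junction", a, b)
        return False
    flank_a = (cells_a - sharers).pop()
    flank_b = (cells_b - sharers).pop()

    # orient: alpha traverses a -> b (keeps a), beta traverses b -> a (keeps b)
    alpha = beta = None
    for cid in sharers:
        loop = mesh.cells[cid]
        n = len(loop)
        for i in range(n):
            if loop[i] == a and loop[(i + 1) % n] == b:
                alpha = cid
            elif loop[i] == b and loop[(i + 1) % n] == a:
                beta = cid
    if alpha is None or beta is None:
        raise MeshError(f"edge ({a}, {b}) has inconsistent orientation")
    if len(mesh.cells[alpha]) <= 3 or len(mesh.cells[beta]) <= 3:
        logger.debug("T1 skipped on edge (%s, %s): a sharer is a triangle", a, b)
        return False

    gate = targets is not None and mech is not None
    incident = sorted({alpha, beta, flank_a, flank_b})
    if gate:
        e_before = _local_energy(mesh, incident, targets, mech)
        saved = (mesh.vertices[a].copy(), mesh.vertices[b].copy(),
                 list(mesh.cells[alpha]), list(mesh.cells[beta]),
                 list(mesh.cells[flank_a]), list(mesh.cells[flank_b]))

    ra, rb = mesh.vertices[a], mesh.vertices[b]
    mid = 0.5 * (ra + rb)
    u = rb - ra
    norm = float(np.hypot(*u))
    if norm < 1e-300:
        u = np.array([1.0, 0.0])
    else:
        u = u / norm
    nvec = np.array([-u[1], u[0]])          # 90-degree CCW rotation
    mesh.vertices[a] = mid + 0.5 * params.l_new * nvec
    mesh.vertices[b] = mid - 0.5 * params.l_new * nvec

    alpha_old = list(mesh.cells[alpha])
    beta_old = list(mesh.cells[beta])
    mesh.cells[alpha].remove(b)
    mesh.cells[beta].remove(a)
    # the insertion side in each flank is fixed by the pre-swap traversal of
    # the sharer that keeps the other endpoint
    _insert_adjacent(mesh.cells[flank_a], a, b, keeper_loop=beta_old)
    _insert_adjacent(mesh.cells[flank_b], b, a, keeper_loop=alpha_old)

    if gate:
        e_after = _local_energy(mesh, incident, targets, mech)
        if e_after > e_before:
            (mesh.vertices[a], mesh.vertices[b],
             mesh.cells[alpha], mesh.cells[beta],
             mesh.cells[flank_a], mesh.cells[flank_b]) = saved
            logger.debug("T1 rejected on edge (%s, %s): dE=%+.3e", a, b, e_after - e_before)
            return False

    if log is not None:
        log.append(mesh.time if now is None else now, "T1",
                   (alpha, beta, flank_a, flank_b), edge=f"{a}-{b}")
    return True


# -- T2 -------------------------------------------------------------------

def apply_T2(mesh: TissueMesh, cell_id: int, params: TopologyParams,
             states: dict | None = None, log: EventLog | None = None,
             now: float | None = None) -> bool:
    """Remove a small 3-sided cell, collapsing it to a vertex at its centroid.

    Cells with more than three sides are never removed here (they must
    first lose sides through T1s); returns False for those.  A triangle
    with at most one neighbouring cell is peeled off without creating a
    replacement vertex.  Any neighbour degenerating below three sides is
    removed in cascade.
    """
    loop = mesh.cells.get(cell_id)
    if loop is None:
        raise LookupError(f"unknown cell id {cell_id}")
    if len(loop) != 3:
        logger.debug("T2 skipped on cell %s: %d sides", cell_id, len(loop))
        return False
    coords = mesh.vertices[np.asarray(loop)]
    if signed_area(coords) >= params.A_T2:
        return False
    tri = set(loop)
    neighbours = [cid for cid, lp in mesh.cells.items()
                  if cid != cell_id and tri & set(lp)]
    removed = [cell_id]
    del mesh.cells[cell_id]
    if len(neighbours) >= 2:
        w = mesh.add_vertex(polygon_centroid(coords))
        for cid in neighbours:
            lp = [w if v in tri else v for v in mesh.cells[cid]]
            dedup = [v for i, v in enumerate(lp) if v != lp[i - 1]]
            mesh.cells[cid] = dedup
    # cascade: peel any neighbour left degenerate
    for cid in neighbours:
        if cid in mesh.cells and len(mesh.cells[cid]) < 3:
            del mesh.cells[cid]
            removed.append(cid)
    if states is not None:
        for cid in removed:
            states.pop(cid, None)
    if log is not None:
        t = mesh.time if now is None else now
        log.append(t, "T2", (cell_id,), area=float(signed_area(coords)))
        for cid in removed[1:]:
            log.append(t, "T2", (cid,), reason="degenerate-neighbour")
    return True


def untangle_collapsed_edges(mesh: TissueMesh, params: TopologyParams,
                             l_check: float | None = None) -> int:
    """Repair micro-slivers at tension-collapsed junctions.

    An interior edge held below the T1 threshold by an energy-rejected swap
    behaves as a near-fourfold vertex; during long integration stretches its
    two endpoints can drift through each other, leaving a self-crossing
    sliver in an incident cell.  Swapping the endpoint positions restores
    simplicity without otherwise perturbing the configuration.  Returns the
    number of edges repaired.
    """
    from shapely.geometry import Polygon

    if l_check is None:
        l_check = params.l_T1
    fixed = 0
    vc = vertex_cells(mesh)
    for (a, b), cids in edge_cells(mesh).items():
        if len(cids) != 2:
            continue
        if float(np.hypot(*(mesh.vertices[b] - mesh.vertices[a]))) >= l_check:
            continue
        incident = set(vc.get(a, ())) | set(vc.get(b, ()))
        bad = [cid for cid in incident
               if not Polygon(mesh.vertices[np.asarray(mesh.cells[cid])]).is_valid]
        if not bad:
            continue
        va, vb = mesh.vertices[a].copy(), mesh.vertices[b].copy()
        mesh.vertices[a], mesh.vertices[b] = vb, va
        still = [cid for cid in incident
                 if not Polygon(mesh.vertices[np.asarray(mesh.cells[cid])]).is_valid]
        if still:
            mesh.vertices[a], mesh.vertices[b] = va, vb
            logger.debug("untangle failed on edge (%s, %s)", a, b)
        else:
            fixed += 1
            logger.debug("untangled collapsed edge (%s, %s)", a, b)
    return fixed


# -- sweep ----------------------------------------------------------------

def sweep_topology(mesh: TissueMesh, params: TopologyParams,
                   states: dict | None = None, log: EventLog | None = None,
                   now: float | None = None, max_iter: int = 200,
                   targets=None, mech=None):
    """Apply eligible T1s (shortest edge first) then T2s until quiescent.

    Deterministic given the mesh: ties are broken by the lowest vertex-id
    pair.  ``targets``/``mech`` are forwarded to :func:`apply_T1` for the
    energy gate.  An edge pair is swapped at most once per sweep.  Returns
    ``(n_events, skipped_edges)`` where ``skipped_edges`` are short interior
    edges that were not (or could not be) swapped — boundary junctions and
    energy-rejected swaps; callers may place those on a cooldown.
    """
    n_events = 0
    skipped: set[tuple[int, int]] = set()
    done: dict[tuple[int, int], int] = {}
    for _ in range(max_iter):
        progressed = False
        # shortest eligible short edge first
        candidates = []
        for (a, b), cids in edge_cells(mesh).items():
            if len(cids) != 2:
                continue
            ln = float(np.hypot(*(mesh.vertices[b] - mesh.vertices[a])))
            if ln < params.l_T1:
                candidates.append((ln, (a, b)))
        candidates.sort(key=lambda c: (c[0], c[1]))
        for _, e in candidates:
            if e in skipped or done.get(e, 0) >= 3:
                continue
            if apply_T1(mesh, e, params, log=log, now=now, targets=targets, mech=mech):
                n_events += 1
                done[e] = done.get(e, 0) + 1
                progressed = True
                break
            skipped.add(e)
        if progressed:
            continue
        # smallest sub-threshold triangle
        tris = []
        for cid, loop in mesh.cells.items():
            if len(loop) == 3:
                a = signed_area(mesh.vertices[np.asarray(loop)])
                if a < params.A_T2:
                    tris.append((a, cid))
        tris.sort()
        for _, cid in tris:
            if apply_T2(mesh, cid, params, states=states, log=log, now=now):
                n_events += 1
                progressed = True
                break
        if not progressed:
            return n_events, skipped
    logger.warning("topology sweep hit the iteration cap (%d); partial result", max_iter)
    return n_events, skipped
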