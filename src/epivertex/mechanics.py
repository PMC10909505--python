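"""Tissue energy, analytic forces and overdamped vertex dynamics.

The energy of a configuration ``r`` is the standard vertex-model functional

    E(r) = sum_cells [ K/2 (A - A0)^2 + Gamma/2 L^2 ] + Lambda * sum_edges l,

with per-cell area A and perimeter L and edge lengths l.  Each *unordered*
edge contributes its line-tension term once (some vertex-model variants
count per cell side; this one does not).  Vertices follow first-order
overdamped dynamics  gamma dr/dt = F = -grad E,  integrated with explicit
forward Euler:  r <- r + (dt/gamma) F.

When the target areas are static the friction coefficient gamma only
rescales time (tau = t/gamma); the symmetry is exact for this integrator
when dt is scaled with gamma, and tests rely on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .mesh import MeshError, TissueMesh

__all__ = ["MechanicalParams", "FlatTissue", "total_energy", "forces", "step", "relax"]

_TINY = 1e-12


@dataclass(frozen=True)
class MechanicalParams:
    """Mechanical constants of the energy functional and its dynamics.

    K : area elasticity (energy / length^4), > 0
    Lambda : line tension (energy / length); may be negative in general
    Gamma : perimeter contractility (energy / length^2)
    gamma : friction coefficient (force * time / length), > 0
    dt : forward-Euler step (time); default 0.05 * gamma / K, which keeps
        the explicit scheme well inside its stability region for the
        parameter regime used here.
    """

    K: float = 1.0
    Lambda: float = 0.05
    Gamma: float = 0.02
    gamma: float = 1.0
    dt: float | None = None

    def __post_init__(self):
        if not self.K > 0:
            raise ValueError("K must be > 0")
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if self.dt is not None and not self.dt > 0:
            raise ValueError("dt must be > 0")
        for name in ("Lambda", "Gamma"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def step_dt(self) -> float:
        return self.dt if self.dt is not None else 0.05 * self.gamma / self.K

    def with_gamma(self, gamma: float) -> "MechanicalParams":
        return replace(self, gamma=gamma)


class FlatTissue:
    """Flat index arrays of a mesh, for vectorised geometry/force evaluation.

    One "slot" per (cell, loop position).  ``slot_edge`` maps a slot to the
    unique undirected edge (v -> next), ``slot_edge_prev`` to (prev -> v),
    so each edge length is computed once per evaluation.
    """

    def __init__(self, mesh: TissueMesh):
        self.cell_ids: list[int] = list(mesh.cells.keys())
        slot_cell, slot_v, slot_next, slot_prev = [], [], [], []
        slot_edge, slot_edge_prev = [], []
        edge_index: dict[tuple[int, int], int] = {}
        edge_a, edge_b, edge_count = [], [], []

        def eidx(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            i = edge_index.get(key)
            if i is None:
                i = len(edge_a)
                edge_index[key] = i
                edge_a.append(key[0])
                edge_b.append(key[1])
                edge_count.append(0)
            edge_count[i] += 1
            return i

        for ci, loop in enumerate(mesh.cells.values()):
            n = len(loop)
            for j, v in enumerate(loop):
                nxt = loop[(j + 1) % n]
                prv = loop[(j - 1) % n]
                slot_cell.append(ci)
                slot_v.append(v)
                slot_next.append(nxt)
                slot_prev.append(prv)
                slot_edge.append(eidx(v, nxt))
            # prev-edge ids are the current-edge ids rolled by one
        slot_edge = np.asarray(slot_edge, dtype=np.int64)
        sep = np.empty_like(slot_edge)
        pos = 0
        for loop in mesh.cells.values():
            n = len(loop)
            sep[pos:pos + n] = np.roll(slot_edge[pos:pos + n], 1)
            pos += n
        slot_edge_prev = sep

        self.slot_cell = np.asarray(slot_cell, dtype=np.int64)
        self.slot_v = np.asarray(slot_v, dtype=np.int64)
        self.slot_next = np.asarray(slot_next, dtype=np.int64)
        self.slot_prev = np.asarray(slot_prev, dtype=np.int64)
        self.slot_edge = slot_edge
        self.slot_edge_prev = slot_edge_prev
        self.edge_a = np.asarray(edge_a, dtype=np.int64)
        self.edge_b = np.asarray(edge_b, dtype=np.int64)
        self.edge_multiplicity = np.asarray(edge_count, dtype=np.int64)
        self.edge_index = edge_index
        self.n_cells = len(self.cell_ids)
        self.n_vertices = mesh.n_vertices

    # -- geometry ---------------------------------------------------------
    def geometry(self, verts: np.ndarray):
        """Per-cell areas and perimeters, per-edge lengths."""
        x, y = verts[:, 0], verts[:, 1]
        elen = np.hypot(x[self.edge_b] - x[self.edge_a], y[self.edge_b] - y[self.edge_a])
        cross = x[self.slot_v] * y[self.slot_next] - x[self.slot_next] * y[self.slot_v]
        areas = 0.5 * np.bincount(self.slot_cell, weights=cross, minlength=self.n_cells)
        perims = np.bincount(self.slot_cell, weights=elen[self.slot_edge], minlength=self.n_cells)
        return areas, perims, elen

    def energy(self, verts: np.ndarray, a0: np.ndarray, p: MechanicalParams) -> float:
        areas, perims, elen = self.geometry(verts)
        return float(0.5 * p.K * np.sum((areas - a0) ** 2)
                     + 0.5 * p.Gamma * np.sum(perims ** 2)
                     + p.Lambda * np.sum(elen))

    def forces(self, verts: np.ndarray, a0: np.ndarray, p: MechanicalParams,
               guard_degenerate: bool = True) -> np.ndarray:
        """Analytic -grad E, shape (n_vertices, 2)."""
        areas, perims, elen = self.geometry(verts)
        if guard_degenerate and elen.size and elen.min() < _TINY:
            raise MeshError("degenerate zero-length edge: force undefined")
        x, y = verts[:, 0], verts[:, 1]
        sv, sn, sp, sc = self.slot_v, self.slot_next, self.slot_prev, self.slot_cell

        # area term: dA/dr_i = 0.5 * (y_next - y_prev, x_prev - x_next)
        ca = (p.K * (areas - a0))[sc]
        fx = -ca * 0.5 * (y[sn] - y[sp])
        fy = -ca * 0.5 * (x[sp] - x[sn])

        # perimeter term: dL/dr_i = u(i - prev) - u(next - i)
        cp = (p.Gamma * perims)[sc]
        lA = np.maximum(elen[self.slot_edge_prev], _TINY)
        lB = np.maximum(elen[self.slot_edge], _TINY)
        fx -= cp * ((x[sv] - x[sp]) / lA - (x[sn] - x[sv]) / lB)
        fy -= cp * ((y[sv] - y[sp]) / lA - (y[sn] - y[sv]) / lB)

        F = np.zeros_like(verts)
        F[:, 0] = np.bincount(sv, weights=fx, minlength=self.n_vertices)
        F[:, 1] = np.bincount(sv, weights=fy, minlength=self.n_vertices)

        # line tension: each unordered edge pulls its endpoints together once
        le = np.maximum(elen, _TINY)
        ux = (x[self.edge_b] - x[self.edge_a]) / le
        uy = (y[self.edge_b] - y[self.edge_a]) / le
        np.add.at(F[:, 0], self.edge_a, p.Lambda * ux)
        np.add.at(F[:, 1], self.edge_a, p.Lambda * uy)
        np.add.at(F[:, 0], self.edge_b, -p.Lambda * ux)
        np.add.at(F[:, 1], self.edge_b, -p.Lambda * uy)
        return F

    def target_array(self, targets, mesh: TissueMesh | None = None) -> np.ndarray:
        """Per-cell A0 array in flat order from a {cell_id: A0} mapping."""
        try:
            return np.array([float(targets[cid]) for cid in self.cell_ids])
        except KeyError as exc:
            raise ValueError(f"missing target area for cell {exc.args[0]!r}") from None


# -- public operations ----------------------------------------------------

def total_energy(mesh: TissueMesh, targets, params: MechanicalParams) -> float:
    """Vertex-model energy of the configuration (see module docstring)."""
    ft = FlatTissue(mesh)
    return ft.energy(mesh.vertices, ft.target_array(targets), params)


def forces(mesh: TissueMesh, targets, params: MechanicalParams) -> np.ndarray:
    """Analytic force field F_i = -grad_i E, one 2-vector per vertex row.

    Orphaned vertex rows get zero force.  Raises :class:`MeshError` if any
    edge has (numerically) zero length.
    """
    ft = FlatTissue(mesh)
    return ft.forces(mesh.vertices, ft.target_array(targets), params)


def step(mesh: TissueMesh, force_field: np.ndarray, params: MechanicalParams) -> TissueMesh:
    """One explicit forward-Euler step r <- r + (dt/gamma) F; advances time by dt.

    Returns a new mesh; the input is untouched.  The step itself never
    repairs geometry: a step that creates a self-intersecting cell is left
    for the topology sweep of the simulation loop to resolve.
    """
    F = np.asarray(force_field, dtype=float)
    if F.shape != mesh.vertices.shape:
        raise ValueError(f"force field shape {F.shape} != vertices shape {mesh.vertices.shape}")
    dt = params.step_dt
    out = mesh.copy()
    out.vertices = mesh.vertices + (dt / params.gamma) * F
    out.time = mesh.time + dt
    return out


def relax(mesh: TissueMesh, targets, params: MechanicalParams,
          tol: float = 1e-8, max_steps: int = 200_000):
    """Iterate Euler steps with static targets until max |F_i| < tol.

    Returns ``(mesh, converged)``.  Non-convergence is reported via the
    flag, not an exception.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    ft = FlatTissue(mesh)
    a0 = ft.target_array(targets)
    verts = mesh.vertices.copy()
    used = np.zeros(mesh.n_vertices, dtype=bool)
    used[np.unique(ft.slot_v)] = True
    mob = params.step_dt / params.gamma
    converged = False
    n = 0
    for n in range(max_steps):
        F = ft.forces(verts, a0, params)
        if np.abs(F[used]).max() < tol:
            converged = True
            break
        verts += mob * F
    out = mesh.copy()
    out.vertices = verts
    out.time = mesh.time + n * params.step_dt
    return out, converged
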