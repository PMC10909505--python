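"""Compiled inner loop of the simulation.

The driver in :mod:`epivertex.pipeline` flattens the mesh once per
topological change and hands the arrays to :func:`advance`, which performs
forward-Euler steps until either the requested horizon is reached or an
event needs Python-side surgery (short interior edge, small triangle, or a
division-ready cell).  The force expressions mirror
:meth:`epivertex.mechanics.FlatTissue.forces` exactly; a test asserts the
two paths agree to machine precision.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# advance() exit statuses
STATUS_TIME = 0      # reached t_end
STATUS_EDGE = 1      # armed interior edge shorter than l_T1
STATUS_TRIANGLE = 2  # 3-sided cell below the T2 area threshold
STATUS_DIVISION = 3  # a cell satisfies the division conditions
STATUS_NONFINITE = 4
STATUS_MAXSTEPS = 5

_TINY = 1e-12


@njit(cache=True)
def geometry(verts, slot_cell, slot_v, slot_next, slot_edge,
             edge_a, edge_b, areas, perims, elen):  # pragma: no cover - exercised via wrappers
    ne = edge_a.shape[0]
    for e in range(ne):
        dx = verts[edge_b[e], 0] - verts[edge_a[e], 0]
        dy = verts[edge_b[e], 1] - verts[edge_a[e], 1]
        elen[e] = np.sqrt(dx * dx + dy * dy)
    areas[:] = 0.0
    perims[:] = 0.0
    for s in range(slot_v.shape[0]):
        v = slot_v[s]
        n = slot_next[s]
        c = slot_cell[s]
        areas[c] += 0.5 * (verts[v, 0] * verts[n, 1] - verts[n, 0] * verts[v, 1])
        perims[c] += elen[slot_edge[s]]


@njit(cache=True)
def forces(verts, slot_cell, slot_v, slot_next, slot_prev, slot_edge, slot_edge_prev,
           edge_a, edge_b, areas, perims, elen, a0,
           K, Lam, Gam, F):  # pragma: no cover - exercised via wrappers
    F[:] = 0.0
    for s in range(slot_v.shape[0]):
        c = slot_cell[s]
        v = slot_v[s]
        nx = slot_next[s]
        pv = slot_prev[s]
        ca = K * (areas[c] - a0[c])
        F[v, 0] -= ca * 0.5 * (verts[nx, 1] - verts[pv, 1])
        F[v, 1] -= ca * 0.5 * (verts[pv, 0] - verts[nx, 0])
        cp = Gam * perims[c]
        lA = elen[slot_edge_prev[s]]
        lB = elen[slot_edge[s]]
        if lA < _TINY:
            lA = _TINY
        if lB < _TINY:
            lB = _TINY
        F[v, 0] -= cp * ((verts[v, 0] - verts[pv, 0]) / lA - (verts[nx, 0] - verts[v, 0]) / lB)
        F[v, 1] -= cp * ((verts[v, 1] - verts[pv, 1]) / lA - (verts[nx, 1] - verts[v, 1]) / lB)
    for e in range(edge_a.shape[0]):
        l = elen[e]
        if l < _TINY:
            l = _TINY
        a = edge_a[e]
        b = edge_b[e]
        ux = (verts[b, 0] - verts[a, 0]) / l
        uy = (verts[b, 1] - verts[a, 1]) / l
        F[a, 0] += Lam * ux
        F[a, 1] += Lam * uy
        F[b, 0] -= Lam * ux
        F[b, 1] -= Lam * uy


@njit(cache=True)
def advance(verts, slot_cell, slot_v, slot_next, slot_prev, slot_edge, slot_edge_prev,
            edge_a, edge_b, edge_armed, edge_lam,
            nsides, birth, tcs, trigger_time,
            K, Gam, gamma, dt, A_f, gate, A_c,
            l_t1, A_t2, t0, t_end, max_steps,
            areas, perims, elen, a0, F):  # pragma: no cover - exercised via wrappers
    """Step until t_end or an event; returns (t, status, n_steps).

    Always performs at least one step when t0 < t_end, so an event the
    Python side could not resolve cannot stall the loop.  Target areas
    follow the cell-cycle schedule A0(age) each step.  Event checks use the
    pre-step geometry (one step of lag, below other discretisation error;
    the Python side recomputes on exit).

    The force expressions are those of :func:`forces`, with the line
    tension folded into the slot pass via ``edge_lam`` = Lambda divided by
    the edge multiplicity (each interior edge is visited by two slots).
    """
    t = t0
    if t >= t_end - 1e-12:
        return t, STATUS_TIME, 0
    nc = areas.shape[0]
    ne = edge_a.shape[0]
    ns = slot_v.shape[0]
    nv = verts.shape[0]
    mob = dt / gamma
    steps = 0
    F[:] = 0.0
    while True:
        # pass 1 - edge lengths + short-edge trigger
        short = False
        for e in range(ne):
            dx = verts[edge_b[e], 0] - verts[edge_a[e], 0]
            dy = verts[edge_b[e], 1] - verts[edge_a[e], 1]
            l = np.sqrt(dx * dx + dy * dy)
            elen[e] = l
            if edge_armed[e] and l < l_t1:
                short = True

        # pass 2 - per-cell area and perimeter
        areas[:] = 0.0
        perims[:] = 0.0
        for s in range(ns):
            v = slot_v[s]
            n = slot_next[s]
            c = slot_cell[s]
            areas[c] += 0.5 * (verts[v, 0] * verts[n, 1] - verts[n, 0] * verts[v, 1])
            perims[c] += elen[slot_edge[s]]

        # pass 3 - schedule, prefactors, triangle/division triggers
        t_new = t + dt
        tri = False
        div = False
        for c in range(nc):
            age = t - birth[c]
            half = 0.5 * tcs[c]
            if age < half:
                a0[c] = 1.0
            else:
                g = 2.0 * age / tcs[c]
                a0[c] = g if g < A_f else A_f
            if nsides[c] == 3 and areas[c] < A_t2:
                tri = True
            if t_new >= trigger_time[c] and (gate == 0 or areas[c] >= A_c):
                div = True

        # pass 4 - forces (area + perimeter + folded tension)
        for s in range(ns):
            c = slot_cell[s]
            v = slot_v[s]
            nx = slot_next[s]
            pv = slot_prev[s]
            ca = K * (areas[c] - a0[c])
            cp = Gam * perims[c]
            lA = elen[slot_edge_prev[s]]
            lB = elen[slot_edge[s]]
            if lA < _TINY:
                lA = _TINY
            if lB < _TINY:
                lB = _TINY
            dxA = (verts[v, 0] - verts[pv, 0]) / lA
            dyA = (verts[v, 1] - verts[pv, 1]) / lA
            dxB = (verts[nx, 0] - verts[v, 0]) / lB
            dyB = (verts[nx, 1] - verts[v, 1]) / lB
            lam = edge_lam[slot_edge[s]]
            F[v, 0] -= ca * 0.5 * (verts[nx, 1] - verts[pv, 1]) + cp * (dxA - dxB) - lam * dxB
            F[v, 1] -= ca * 0.5 * (verts[pv, 0] - verts[nx, 0]) + cp * (dyA - dyB) - lam * dyB
            F[nx, 0] -= lam * dxB
            F[nx, 1] -= lam * dyB

        # pass 5 - Euler update, reset force accumulator
        for i in range(nv):
            verts[i, 0] += mob * F[i, 0]
            verts[i, 1] += mob * F[i, 1]
            F[i, 0] = 0.0
            F[i, 1] = 0.0
        t = t_new
        steps += 1

        if short:
            return t, STATUS_EDGE, steps
        if tri:
            return t, STATUS_TRIANGLE, steps
        if div:
            return t, STATUS_DIVISION, steps
        if t >= t_end - 1e-12:
            return t, STATUS_TIME, steps
        if steps >= max_steps:
            return t, STATUS_MAXSTEPS, steps
        if steps % 256 == 0:
            ok = True
            for i in range(nv):
                if not (np.isfinite(verts[i, 0]) and np.isfinite(verts[i, 1])):
                    ok = False
                    break
            if not ok:
                return t, STATUS_NONFINITE, steps
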