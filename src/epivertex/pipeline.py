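"""Experiment layer: full simulation loop, morphology/growth metrics,
friction sweeps and the critical-area ablation.

The main loop alternates a compiled forward-Euler stretch (``_kernels.advance``)
with Python-side event handling: per step the kernel computes forces,
updates vertices, and watches for (i) short interior edges, (ii) small
triangles, (iii) division-ready cells.  On any of those it returns, the
topology sweep and division surgery run, the flat arrays are rebuilt, and
integration resumes.  Everything stochastic draws from one
``numpy.random.Generator`` seeded from the config, so runs are bit
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import _kernels
from .cellcycle import (CellCycleParams, CellState, divide_cell, sample_tc,
                        target_area)
from .growth import GrowthEstimate, IntrinsicCycleDistribution, solve_euler_lotka
from .mechanics import FlatTissue, MechanicalParams
from .mesh import CellGeometry, TissueMesh, build_hexagonal_lattice, hexagon_side_for_area
from .topology import (EventLog, TopologyParams, sweep_topology,
                       untangle_collapsed_edges)

__all__ = ["SimulationConfig", "SimulationResult", "run_simulation", "shape_index",
           "morphology_summary", "fit_growth_rate", "friction_sweep", "replicate_seed"]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulation run (flat, YAML-serialisable).

    Defaults are the reference parameter set of the study: K=1, Lambda=0.05,
    Gamma=0.02, gamma=1, A_f=2, A_c=0.78*A_f, Tc=388, epsilon=0.8, a
    100-cell hexagonal lattice of unit-area cells, duration 3200 (~10 Tc).
    """

    K: float = 1.0
    Lambda: float = 0.05
    Gamma: float = 0.02
    gamma: float = 1.0
    dt: float | None = None        # default 0.05 * gamma / K
    Tc: float = 388.0
    epsilon: float = 0.8
    A_f: float = 2.0
    A_c: float = 1.56
    with_area_gate: bool = True
    l_T1: float = 0.05
    l_new: float = 0.06
    A_T2: float = 0.02
    n0: int = 100
    initial_cell_area: float = 1.0
    t_max: float = 3200.0
    max_cells: int | None = None
    seed: int = 0
    snapshot_every: float | None = None   # default Tc / 10
    keep_snapshots: bool = False

    def __post_init__(self):
        if self.t_max is None and self.max_cells is None:
            raise ValueError("need a stop condition: t_max and/or max_cells")

    @property
    def mech(self) -> MechanicalParams:
        return MechanicalParams(K=self.K, Lambda=self.Lambda, Gamma=self.Gamma,
                                gamma=self.gamma, dt=self.dt)

    @property
    def cycle(self) -> CellCycleParams:
        return CellCycleParams(Tc=self.Tc, epsilon=self.epsilon, A_f=self.A_f,
                               A_c=self.A_c, with_area_gate=self.with_area_gate)

    @property
    def topo(self) -> TopologyParams:
        return TopologyParams(l_T1=self.l_T1, l_new=self.l_new, A_T2=self.A_T2)

    @property
    def cadence(self) -> float:
        return self.snapshot_every if self.snapshot_every is not None else self.Tc / 10.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SimulationResult:
    config: SimulationConfig
    mesh: TissueMesh
    states: dict[int, CellState]
    log: EventLog
    metrics: pd.DataFrame
    snapshots: list = field(default_factory=list)

    # -- convenience views -------------------------------------------------
    def cell_areas(self) -> np.ndarray:
        ft = FlatTissue(self.mesh)
        areas, _, _ = ft.geometry(self.mesh.vertices)
        return areas

    def cell_shape_indices(self) -> np.ndarray:
        ft = FlatTissue(self.mesh)
        areas, perims, _ = ft.geometry(self.mesh.vertices)
        return perims / np.sqrt(areas)

    def ages(self, now: float | None = None) -> np.ndarray:
        t = self.mesh.time if now is None else now
        return np.array([t - self.states[cid].birth_time for cid in self.mesh.cells])

    def division_table(self) -> pd.DataFrame:
        return self.log.divisions()


def shape_index(geometry: CellGeometry) -> float:
    """Dimensionless shape index P / sqrt(A) (a jamming/rigidity indicator)."""
    if not geometry.area > 0:
        raise ValueError("shape index undefined for non-positive area")
    return geometry.perimeter / math.sqrt(geometry.area)


def morphology_summary(mesh: TissueMesh) -> pd.DataFrame:
    """Per-neighbour-class morphology table.

    One row per polygon class n: frequency, mean area A_n, normalised
    mean area A_n / Abar, and mean shape index s_n = P_n / sqrt(A_n per
    cell).  Frequencies sum to 1 and sum_n freq(n) * A_n = Abar.
    """
    if mesh.n_cells < 1:
        raise ValueError("need at least one cell")
    ft = FlatTissue(mesh)
    areas, perims, _ = ft.geometry(mesh.vertices)
    nsides = np.array([len(mesh.cells[cid]) for cid in ft.cell_ids])
    df = pd.DataFrame({"n": nsides, "area": areas, "shape_index": perims / np.sqrt(areas)})
    mean_area = float(areas.mean())
    out = (df.groupby("n")
             .agg(count=("area", "size"), mean_area=("area", "mean"),
                  mean_shape_index=("shape_index", "mean"))
             .reset_index())
    out["frequency"] = out["count"] / len(df)
    out["area_ratio"] = out["mean_area"] / mean_area
    return out


# -- simulation driver ----------------------------------------------------

class _RunState:
    """Flat arrays + event bookkeeping between kernel calls."""

    def __init__(self, mesh: TissueMesh, states: dict[int, CellState], Lambda: float):
        self.mesh = mesh
        self.states = states
        self.Lambda = float(Lambda)
        self.defer: dict[int, float] = {}          # cell id -> retry-not-before time
        self.cooldown: dict[tuple[int, int], float] = {}  # edge -> re-arm time
        self.rebuild(0.0)

    def rebuild(self, now: float) -> None:
        mesh, states = self.mesh, self.states
        if len(self.cooldown) > 10000:
            self.cooldown = {k: v for k, v in self.cooldown.items() if v > now}
        ft = FlatTissue(mesh)
        self.ft = ft
        nc = ft.n_cells
        self.nsides = np.array([len(mesh.cells[cid]) for cid in ft.cell_ids], dtype=np.int64)
        self.birth = np.array([states[cid].birth_time for cid in ft.cell_ids])
        self.tcs = np.array([states[cid].tc for cid in ft.cell_ids])
        trig = self.birth + self.tcs
        for i, cid in enumerate(ft.cell_ids):
            d = self.defer.get(cid)
            if d is not None and d > trig[i]:
                trig[i] = d
        self.trigger_time = trig
        # arm interior edges between full tri-junctions, outside cooldown
        from .mesh import vertex_cells
        vc = vertex_cells(mesh)
        armed = np.zeros(ft.edge_a.size, dtype=np.uint8)
        for e in range(ft.edge_a.size):
            a, b = int(ft.edge_a[e]), int(ft.edge_b[e])
            if ft.edge_multiplicity[e] == 2 and len(vc[a]) == 3 and len(vc[b]) == 3:
                cd = self.cooldown.get((a, b), -np.inf)
                if cd <= now:
                    armed[e] = 1
        self.edge_armed = armed
        # line tension split across the slots visiting each edge
        self.edge_lam = self.Lambda / ft.edge_multiplicity.astype(float)
        self.areas = np.empty(nc)
        self.perims = np.empty(nc)
        self.elen = np.empty(ft.edge_a.size)
        self.a0 = np.empty(nc)
        self.F = np.empty_like(mesh.vertices)


def _resolve_events(rs: _RunState, now: float, config: SimulationConfig,
                    log: EventLog, rng: np.random.Generator) -> bool:
    """Topology sweep then division checks; returns True if anything changed."""
    mesh, states = rs.mesh, rs.states
    topo, cycle = config.topo, config.cycle
    mech = config.mech
    dt = mech.step_dt

    targets = {cid: target_area(now - states[cid].birth_time, states[cid].tc, cycle.A_f)
               for cid in mesh.cells}
    n_topo, _ = sweep_topology(mesh, topo, states=states, log=log, now=now,
                               targets=targets, mech=mech)

    # any interior edge still below threshold (boundary junction, rejected
    # swap, or left over) goes on cooldown so the kernel makes progress
    from .mesh import edge_cells
    for (a, b), cids in edge_cells(mesh).items():
        if len(cids) == 2:
            ln = float(np.hypot(*(mesh.vertices[b] - mesh.vertices[a])))
            if ln < topo.l_T1:
                rs.cooldown[(a, b)] = now + 1000.0 * dt

    changed = n_topo > 0
    # division checks against current geometry
    ft = FlatTissue(mesh)
    areas, _, _ = ft.geometry(mesh.vertices)
    area_of = dict(zip(ft.cell_ids, areas))
    for cid in list(mesh.cells.keys()):
        st = states.get(cid)
        if st is None or cid not in mesh.cells:
            continue
        if now - st.birth_time < st.tc:
            continue
        if rs.defer.get(cid, -np.inf) > now:
            continue
        if cycle.with_area_gate and area_of[cid] < cycle.A_c:
            continue
        from shapely.geometry import Polygon
        if not Polygon(mesh.vertices[np.asarray(mesh.cells[cid])]).is_valid:
            untangle_collapsed_edges(mesh, topo, l_check=2 * config.l_new)
        out = divide_cell(mesh, st, now, cycle, rng, log=log, min_edge=config.l_new)
        if out is None:
            rs.defer[cid] = now + 50.0 * dt
            continue
        _, (sa, sb) = out
        del states[cid]
        rs.defer.pop(cid, None)
        states[sa.cell_id] = sa
        states[sb.cell_id] = sb
        changed = True
    return changed


def _metrics_row(rs: _RunState, now: float, log: EventLog) -> dict:
    mesh, states = rs.mesh, rs.states
    ft = FlatTissue(mesh)
    areas, perims, _ = ft.geometry(mesh.vertices)
    ages = np.array([now - states[cid].birth_time for cid in ft.cell_ids])
    return {
        "time": now,
        "n_cells": mesh.n_cells,
        "area_mean": float(areas.mean()),
        "area_sd": float(areas.std(ddof=0)),
        "perimeter_mean": float(perims.mean()),
        "shape_index_mean": float((perims / np.sqrt(areas)).mean()),
        "age_mean": float(ages.mean()),
        "n_divisions": log.count("division"),
        "n_T1": log.count("T1"),
        "n_T2": log.count("T2"),
    }


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run the vertex model from a fresh hexagonal lattice.

    Stops at ``t_max`` and/or when the tissue reaches ``max_cells``.
    Returns the final mesh and states, the event log, and the per-snapshot
    metrics table (cadence ``snapshot_every``, default Tc/10).
    """
    rng = np.random.default_rng(config.seed)
    side = hexagon_side_for_area(config.initial_cell_area)
    mesh = build_hexagonal_lattice(config.n0, side)
    cycle = config.cycle
    states = {cid: CellState(cell_id=cid, birth_time=0.0,
                             tc=float(sample_tc(cycle, rng)), parent_id=None)
              for cid in mesh.cells}
    log = EventLog()
    mech = config.mech
    dt = mech.step_dt
    rs = _RunState(mesh, states, mech.Lambda)

    rows = [_metrics_row(rs, 0.0, log)]
    snapshots = []
    t = 0.0
    next_snap = config.cadence
    max_kernel_steps = 5_000_000

    def stop() -> bool:
        if config.t_max is not None and t >= config.t_max - 1e-9:
            return True
        return config.max_cells is not None and mesh.n_cells >= config.max_cells

    while not stop():
        t_end = next_snap if config.t_max is None else min(next_snap, config.t_max)
        t_new, status, _ = _kernels.advance(
            mesh.vertices, rs.ft.slot_cell, rs.ft.slot_v, rs.ft.slot_next,
            rs.ft.slot_prev, rs.ft.slot_edge, rs.ft.slot_edge_prev,
            rs.ft.edge_a, rs.ft.edge_b, rs.edge_armed, rs.edge_lam,
            rs.nsides, rs.birth, rs.tcs, rs.trigger_time,
            mech.K, mech.Gamma, mech.gamma, dt,
            cycle.A_f, 1 if cycle.with_area_gate else 0, cycle.A_c,
            config.l_T1, config.A_T2, t, t_end, max_kernel_steps,
            rs.areas, rs.perims, rs.elen, rs.a0, rs.F)
        t = t_new
        mesh.time = t
        if status == _kernels.STATUS_NONFINITE:
            raise RuntimeError(f"non-finite vertex positions at t={t:g} "
                               f"(gamma={config.gamma}, dt={dt}); reduce dt")
        if status in (_kernels.STATUS_EDGE, _kernels.STATUS_TRIANGLE,
                      _kernels.STATUS_DIVISION):
            _resolve_events(rs, t, config, log, rng)
            rs.rebuild(t)
        elif status == _kernels.STATUS_TIME:
            if t >= next_snap - 1e-9:
                rows.append(_metrics_row(rs, t, log))
                if config.keep_snapshots:
                    snapshots.append((t, mesh.copy(),
                                      {cid: replace(st) for cid, st in states.items()}))
                next_snap += config.cadence
        # STATUS_MAXSTEPS: just loop again

    for _ in range(3):
        if untangle_collapsed_edges(mesh, config.topo, l_check=2 * config.l_new) == 0:
            break
    rows.append(_metrics_row(rs, t, log))
    metrics = pd.DataFrame(rows).drop_duplicates(subset="time", keep="last").reset_index(drop=True)
    return SimulationResult(config=config, mesh=mesh, states=states, log=log,
                            metrics=metrics, snapshots=snapshots)


# -- analysis -------------------------------------------------------------

def fit_growth_rate(metrics: pd.DataFrame, transient: float | None = None,
                    Tc: float = 388.0) -> GrowthEstimate:
    """Least-squares slope of ln N(t) vs t, excluding the early transient.

    ``transient`` defaults to one mean cycle time Tc (the initial lattice is
    age-synchronised at t=0; growth is only exponential once the age
    structure has randomised).  A non-growing or too-short trajectory is
    returned flagged (``converged=False``) rather than raising.
    """
    t0 = (Tc if transient is None else transient)
    sel = metrics[(metrics["time"] >= t0) & (metrics["n_cells"] > 0)]
    if len(sel) < 5 or sel["n_cells"].iloc[-1] < 2 * sel["n_cells"].iloc[0]:
        res = stats.linregress(sel["time"], np.log(sel["n_cells"])) if len(sel) >= 2 else None
        return GrowthEstimate(k_sto=None if res is None else float(res.slope),
                              method="exponential_fit", converged=False,
                              stderr=None if res is None else float(res.stderr))
    res = stats.linregress(sel["time"], np.log(sel["n_cells"]))
    return GrowthEstimate(k_sto=float(res.slope), method="exponential_fit",
                          stderr=float(res.stderr))


def replicate_seed(master_seed: int, param_index: int, replicate: int) -> int:
    """Deterministic per-replicate seed derived from (master, parameter, replicate)."""
    ss = np.random.SeedSequence([int(master_seed), int(param_index), int(replicate)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def friction_sweep(base_config: SimulationConfig, gammas, n_replicates: int = 5,
                   master_seed: int = 0, dt_over_gamma: float | None = None) -> dict:
    """Run replicates across friction values and collect comparison tables.

    For each gamma: per-replicate summaries (final tissue size/time, mean
    apical area, shape index, division ages/areas, T2 count, fitted growth
    rate) plus pooled arrays for distribution-level comparisons.  The three
    theory rates (intrinsic Euler-Lotka, deterministic from the measured
    mean cycle, and the age-structure estimate from the final snapshot) are
    attached per gamma.
    """
    gammas = [float(g) for g in gammas]
    if len(gammas) < 2:
        raise ValueError("need at least two gamma values to compare")
    from .growth import ksto_from_age_structure

    out: dict = {"gammas": list(gammas), "per_gamma": {}}
    intrinsic = IntrinsicCycleDistribution(base_config.epsilon, base_config.Tc)
    k13 = solve_euler_lotka(intrinsic)
    for gi, g in enumerate(gammas):
        reps = []
        for r in range(n_replicates):
            cfg = replace(base_config, gamma=float(g),
                          dt=None if dt_over_gamma is None else dt_over_gamma * float(g),
                          seed=replicate_seed(master_seed, gi, r))
            res = run_simulation(cfg)
            div = res.division_table()
            fit = fit_growth_rate(res.metrics, Tc=cfg.Tc)
            reps.append({
                "seed": cfg.seed,
                "final_time": res.mesh.time,
                "n_cells": res.mesh.n_cells,
                "areas": res.cell_areas(),
                "shape_indices": res.cell_shape_indices(),
                "ages": res.ages(),
                "division_ages": div["parent_age"].to_numpy() if len(div) else np.empty(0),
                "division_areas": div["parent_area"].to_numpy() if len(div) else np.empty(0),
                "n_T2": res.log.count("T2"),
                "n_T1": res.log.count("T1"),
                "n_divisions": res.log.count("division"),
                "k_fit": fit.k_sto,
                "k_fit_stderr": fit.stderr,
                "metrics": res.metrics,
            })
        # cycle-averaged mean apical area: cell-weighted over the snapshots of
        # the last intrinsic cycle, removing the division-wave phase artifact
        # (residual age synchrony makes the instantaneous mean oscillate with
        # period ~Tc at desk scale)
        for r in reps:
            m = r["metrics"]
            win = m[m["time"] >= r["final_time"] - base_config.Tc]
            r["mean_area_cycle"] = float((win["area_mean"] * win["n_cells"]).sum()
                                         / win["n_cells"].sum())
        pooled_areas = np.concatenate([r["areas"] for r in reps])
        pooled_si = np.concatenate([r["shape_indices"] for r in reps])
        pooled_div_age = np.concatenate([r["division_ages"] for r in reps])
        pooled_div_area = np.concatenate([r["division_areas"] for r in reps])
        pooled_ages = np.concatenate([r["ages"] for r in reps])
        mean_cycle = float(pooled_div_age.mean()) if pooled_div_age.size else float("nan")
        age_est = ksto_from_age_structure(pooled_ages, delta=0.02 * base_config.Tc,
                                          rng=np.random.default_rng(master_seed)) \
            if pooled_ages.size >= 100 else None
        out["per_gamma"][float(g)] = {
            "replicates": reps,
            "mean_area": float(pooled_areas.mean()),
            "mean_area_cycle": float(np.mean([r["mean_area_cycle"] for r in reps])),
            "mean_shape_index": float(pooled_si.mean()),
            "mean_division_age": mean_cycle,
            "mean_division_area": float(pooled_div_area.mean()) if pooled_div_area.size else float("nan"),
            "median_division_area": float(np.median(pooled_div_area)) if pooled_div_area.size else float("nan"),
            "pooled_areas": pooled_areas,
            "pooled_division_ages": pooled_div_age,
            "pooled_division_areas": pooled_div_area,
            "total_T2": int(sum(r["n_T2"] for r in reps)),
            "k_intrinsic": k13,
            "k_det_measured": (math.log(2.0) / mean_cycle) if mean_cycle == mean_cycle else float("nan"),
            "k_fit_mean": float(np.mean([r["k_fit"] for r in reps if r["k_fit"] is not None])),
            "k_age_structure": None if age_est is None else age_est.k_sto,
        }
    gs = [float(g) for g in out["gammas"]]
    out["summary"] = pd.DataFrame([
        {"gamma": g, **{k: v for k, v in out["per_gamma"][g].items()
                        if isinstance(v, (int, float))}}
        for g in gs
    ])
    return out
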