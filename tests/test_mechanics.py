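import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize_scalar

from epivertex.mechanics import (FlatTissue, MechanicalParams, forces, relax,
                                 step, total_energy)
from epivertex.mesh import (MeshError, TissueMesh, build_hexagonal_lattice,
                            cell_geometry)

from conftest import UNIT_SIDE, jittered_lattice

TABLE = MechanicalParams(K=1.0, Lambda=0.05, Gamma=0.02)
HEX_AREA = 1.5 * math.sqrt(3.0)


def hexagon_energy_1d(side: float, a0: float, p: MechanicalParams) -> float:
    """Energy of a single regular hexagon as a function of its side (oracle)."""
    area = HEX_AREA * side ** 2
    return 0.5 * p.K * (area - a0) ** 2 + 0.5 * p.Gamma * (6 * side) ** 2 + p.Lambda * 6 * side


class TestEnergy:
    def test_closed_form_single_hexagon(self):
        mesh = build_hexagonal_lattice(1, 1.0)
        # K/2 (A-1)^2 + Gamma/2 L^2 + Lambda * 6
        expected = 0.5 * (HEX_AREA - 1.0) ** 2 + 0.01 * 36.0 + 0.05 * 6.0
        assert total_energy(mesh, {0: 1.0}, TABLE) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.93692, abs=5e-6)

    def test_zero_constants_zero_energy(self):
        mesh = jittered_lattice(5, 0)
        p = MechanicalParams(K=1e-300, Lambda=0.0, Gamma=0.0)
        assert total_energy(mesh, {c: cell_geometry(mesh, c).area for c in mesh.cells}, p) \
            == pytest.approx(0.0, abs=1e-12)

    def test_elastic_minimum_at_target(self):
        mesh = build_hexagonal_lattice(4, UNIT_SIDE)
        p = MechanicalParams(K=1.0, Lambda=0.0, Gamma=0.0)
        assert total_energy(mesh, {c: 1.0 for c in mesh.cells}, p) == pytest.approx(0.0, abs=1e-18)

    def test_missing_target_errors(self):
        mesh = build_hexagonal_lattice(2, 1.0)
        with pytest.raises(ValueError, match="target"):
            total_energy(mesh, {0: 1.0}, TABLE)

    def test_shared_edges_counted_once(self):
        # 2 hexagons: 11 edges total (12 sides - 1 shared)
        mesh = build_hexagonal_lattice(2, 1.0)
        p = MechanicalParams(K=1e-300, Lambda=1.0, Gamma=0.0)
        e = total_energy(mesh, {c: 0.0 for c in mesh.cells}, p)
        assert e == pytest.approx(11.0, rel=1e-12)


class TestForces:
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_finite_differences(self, seed):
        """Analytic gradient vs central finite differences of the energy."""
        mesh = jittered_lattice(5, seed)
        targets = {c: 1.3 for c in mesh.cells}
        F = forces(mesh, targets, TABLE)
        ft = FlatTissue(mesh)
        a0 = ft.target_array(targets)
        h = 1e-6
        r = np.random.default_rng(seed)
        for i in r.choice(np.unique(ft.slot_v), size=6, replace=False):
            for d in range(2):
                vp = mesh.vertices.copy(); vp[i, d] += h
                vm = mesh.vertices.copy(); vm[i, d] -= h
                fd = -(ft.energy(vp, a0, TABLE) - ft.energy(vm, a0, TABLE)) / (2 * h)
                assert abs(fd - F[i, d]) < 1e-5

    def test_total_force_is_zero(self):
        """Translation invariance of the energy implies sum_i F_i = 0."""
        mesh = jittered_lattice(7, 99)
        F = forces(mesh, {c: 1.5 for c in mesh.cells}, TABLE)
        assert np.abs(F.sum(axis=0)).max() < 1e-10

    def test_translation_invariance(self):
        mesh = jittered_lattice(5, 7)
        targets = {c: 1.2 for c in mesh.cells}
        F1 = forces(mesh, targets, TABLE)
        shifted = mesh.copy()
        shifted.vertices = mesh.vertices + np.array([3.7, -1.2])
        F2 = forces(shifted, targets, TABLE)
        assert np.allclose(F1, F2, atol=1e-9)

    def test_equilibrium_hexagon_has_zero_force(self):
        """The regular hexagon minimising the 1D energy oracle is force-free."""
        res = minimize_scalar(hexagon_energy_1d, bounds=(0.1, 2.0), args=(1.0, TABLE),
                              method="bounded", options={"xatol": 1e-12})
        mesh = build_hexagonal_lattice(1, res.x)
        F = forces(mesh, {0: 1.0}, TABLE)
        assert np.abs(F).max() < 1e-8

    def test_degenerate_edge_guard(self):
        mesh = TissueMesh([[0, 0], [1, 0], [1, 1], [1, 1 + 1e-15]],
                          {0: [0, 1, 2, 3]})
        with pytest.raises(MeshError, match="degenerate"):
            forces(mesh, {0: 1.0}, TABLE)

    def test_kernel_matches_numpy_path(self):
        """The compiled force kernel and the numpy reference agree exactly."""
        from epivertex import _kernels

        mesh = jittered_lattice(7, 11)
        targets = {c: 1.4 for c in mesh.cells}
        ft = FlatTissue(mesh)
        a0 = ft.target_array(targets)
        F_np = ft.forces(mesh.vertices, a0, TABLE)
        areas = np.empty(ft.n_cells); perims = np.empty(ft.n_cells)
        elen = np.empty(ft.edge_a.size); F = np.zeros_like(mesh.vertices)
        _kernels.geometry(mesh.vertices, ft.slot_cell, ft.slot_v, ft.slot_next,
                          ft.slot_edge, ft.edge_a, ft.edge_b, areas, perims, elen)
        _kernels.forces(mesh.vertices, ft.slot_cell, ft.slot_v, ft.slot_next,
                        ft.slot_prev, ft.slot_edge, ft.slot_edge_prev,
                        ft.edge_a, ft.edge_b, areas, perims, elen, a0,
                        TABLE.K, TABLE.Lambda, TABLE.Gamma, F)
        a_np, p_np, _ = ft.geometry(mesh.vertices)
        assert np.allclose(areas, a_np, rtol=1e-13)
        assert np.allclose(perims, p_np, rtol=1e-13)
        assert np.allclose(F, F_np, atol=1e-12)


class TestDynamics:
    def test_zero_force_is_identity(self):
        mesh = build_hexagonal_lattice(3, 1.0)
        out = step(mesh, np.zeros_like(mesh.vertices), TABLE)
        assert np.array_equal(out.vertices, mesh.vertices)
        assert out.time == pytest.approx(mesh.time + TABLE.step_dt)

    def test_gamma_dt_scaling(self):
        """One step at (gamma=2, dt) equals one step at (gamma=1, dt/2)."""
        mesh = jittered_lattice(4, 5)
        targets = {c: 1.5 for c in mesh.cells}
        p2 = MechanicalParams(gamma=2.0, dt=0.05)
        p1 = MechanicalParams(gamma=1.0, dt=0.025)
        F = forces(mesh, targets, p2)
        out2 = step(mesh, F, p2)
        out1 = step(mesh, F, p1)
        assert np.allclose(out2.vertices, out1.vertices, atol=0.0)

    def test_friction_time_rescaling_symmetry(self):
        """With static targets, the trajectory at (gamma, t) equals the one at
        (1, t/gamma) sampled at rescaled times."""
        mesh = jittered_lattice(5, 21)
        targets = {c: 1.3 for c in mesh.cells}
        g = 4.0
        n_steps = 200
        pg = MechanicalParams(gamma=g, dt=0.05 * g)
        p1 = MechanicalParams(gamma=1.0, dt=0.05)
        ma, mb = mesh.copy(), mesh.copy()
        for _ in range(n_steps):
            ma = step(ma, forces(ma, targets, pg), pg)
            mb = step(mb, forces(mb, targets, p1), p1)
        assert np.abs(ma.vertices - mb.vertices).max() < 1e-8
        assert ma.time == pytest.approx(g * mb.time)

    def test_energy_nonincreasing(self):
        mesh = jittered_lattice(7, 13)
        targets = {c: 1.2 for c in mesh.cells}
        p = MechanicalParams(dt=0.01)  # dt = 0.01 * gamma / K
        ft = FlatTissue(mesh)
        a0 = ft.target_array(targets)
        m = mesh
        energies = [ft.energy(m.vertices, a0, p)]
        for _ in range(300):
            m = step(m, forces(m, targets, p), p)
            energies.append(ft.energy(m.vertices, a0, p))
        diffs = np.diff(energies)
        assert (diffs <= 1e-12).all()


class TestRelax:
    def test_relaxes_to_1d_oracle_minimum(self):
        res = minimize_scalar(hexagon_energy_1d, bounds=(0.1, 2.0), args=(1.0, TABLE),
                              method="bounded", options={"xatol": 1e-12})
        min_area = HEX_AREA * res.x ** 2
        mesh = build_hexagonal_lattice(1, UNIT_SIDE)
        r = np.random.default_rng(0)
        mesh.vertices = mesh.vertices + r.normal(0, 0.02, mesh.vertices.shape)
        out, converged = relax(mesh, {0: 1.0}, TABLE, tol=1e-10)
        assert converged
        assert cell_geometry(out, 0).area == pytest.approx(min_area, abs=1e-4)

    def test_converged_input_returns_immediately(self):
        mesh = build_hexagonal_lattice(1, 1.0)
        out, converged = relax(mesh, {0: 1.0}, TABLE, tol=math.inf)
        assert converged
        assert np.array_equal(out.vertices, mesh.vertices)

    def test_nonconvergence_flag(self):
        mesh = jittered_lattice(3, 2)
        out, converged = relax(mesh, {c: 1.0 for c in mesh.cells}, TABLE,
                               tol=1e-30, max_steps=5)
        assert not converged
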