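import numpy as np
import pytest

from epivertex.mesh import (TissueMesh, build_hexagonal_lattice, cell_geometry,
                            edge_cells, signed_area, validate_mesh)
from epivertex.topology import (EventLog, TopologyParams, apply_T1, apply_T2,
                                sweep_topology)

from conftest import UNIT_SIDE

PARAMS = TopologyParams(l_T1=0.2, l_new=0.24, A_T2=0.1)


def pinwheel(edge_len=0.1):
    """Four cells around a short vertical central edge a-b: two hexagons
    (left/right) sharing it, two pentagons (top/bottom) flanking it."""
    h = edge_len / 2
    verts = [
        [0.0, h],            # 0 = a (top of central edge)
        [0.0, -h],           # 1 = b
        [-0.5, 0.6], [-1.0, 0.3], [-1.0, -0.3], [-0.5, -0.6],   # left
        [0.5, -0.6], [1.0, -0.3], [1.0, 0.3], [0.5, 0.6],       # right
        [0.25, 1.0], [-0.25, 1.0],                              # top
        [-0.25, -1.0], [0.25, -1.0],                            # bottom
    ]
    cells = {
        0: [1, 0, 2, 3, 4, 5],       # left hexagon (traverses b -> a)
        1: [0, 1, 6, 7, 8, 9],       # right hexagon (traverses a -> b)
        2: [9, 10, 11, 2, 0],        # top pentagon (contains a only)
        3: [5, 12, 13, 6, 1],        # bottom pentagon (contains b only)
    }
    return TissueMesh(verts, cells)


def shrunken_center(scale=0.05):
    """Lattice patch with one fully interior cell contracted to a tiny hexagon."""
    mesh = build_hexagonal_lattice(16, UNIT_SIDE)
    ec = edge_cells(mesh)
    shared = {cid: 0 for cid in mesh.cells}
    for cids in ec.values():
        if len(cids) == 2:
            for c in cids:
                shared[c] += 1
    center = max(shared, key=shared.get)
    assert shared[center] == 6  # all six edges interior
    loop = mesh.cells[center]
    coords = mesh.vertices[np.asarray(loop)]
    c = coords.mean(axis=0)
    for v, xy in zip(loop, coords):
        mesh.vertices[v] = c + scale * (xy - c)
    return mesh, center


class TestT1:
    def test_pinwheel_fixture_is_valid(self):
        validate_mesh(pinwheel())

    def test_swaps_adjacency_and_side_counts(self):
        mesh = pinwheel()
        log = EventLog()
        sides_before = sorted(len(l) for l in mesh.cells.values())
        assert sides_before == [5, 5, 6, 6]
        assert apply_T1(mesh, (0, 1), PARAMS, log=log)
        validate_mesh(mesh)
        assert sorted(len(l) for l in mesh.cells.values()) == [5, 5, 6, 6]
        # hexagons (0,1) lost a side, pentagons (2,3) gained one
        assert len(mesh.cells[0]) == 5 and len(mesh.cells[1]) == 5
        assert len(mesh.cells[2]) == 6 and len(mesh.cells[3]) == 6
        # the central edge is now shared by the former flanks
        assert sorted(edge_cells(mesh)[(0, 1)]) == [2, 3]
        # re-formed edge has length l_new
        assert np.hypot(*(mesh.vertices[1] - mesh.vertices[0])) == pytest.approx(PARAMS.l_new)
        assert log.count("T1") == 1

    @staticmethod
    def _neighbour_pairs(mesh):
        return {tuple(sorted(cids)) for cids in edge_cells(mesh).values()
                if len(cids) == 2}

    def test_involution_restores_adjacency(self):
        mesh = pinwheel()
        pairs0 = self._neighbour_pairs(mesh)
        sides0 = {cid: len(l) for cid, l in mesh.cells.items()}
        apply_T1(mesh, (0, 1), PARAMS)
        assert self._neighbour_pairs(mesh) != pairs0
        apply_T1(mesh, (0, 1), PARAMS)
        assert self._neighbour_pairs(mesh) == pairs0
        assert {cid: len(l) for cid, l in mesh.cells.items()} == sides0
        validate_mesh(mesh)

    def test_total_area_change_is_local(self):
        mesh = pinwheel(edge_len=0.04)
        total0 = sum(cell_geometry(mesh, c).area for c in mesh.cells)
        apply_T1(mesh, (0, 1), TopologyParams(l_T1=0.05, l_new=0.06, A_T2=0.01))
        total1 = sum(cell_geometry(mesh, c).area for c in mesh.cells)
        assert abs(total1 - total0) < 1e-6 * total0

    def test_boundary_edge_skipped(self):
        mesh = build_hexagonal_lattice(2, 1.0)
        before = {cid: list(l) for cid, l in mesh.cells.items()}
        # every edge of a 2-cell patch touches the boundary
        for e in edge_cells(mesh):
            assert not apply_T1(mesh, e, PARAMS)
        assert mesh.cells == before

    def test_energy_gate_matches_energy_difference(self):
        """With targets/mech given, a swap is applied iff it lowers the local
        energy; the decision agrees with an independent full-mesh energy
        evaluation of the forced (ungated) swap."""
        from epivertex.mechanics import MechanicalParams, total_energy

        # the swap transfers area from the sharers to the flanks, so elastic
        # targets wanting exactly that make it downhill, the reverse uphill
        mesh = pinwheel(edge_len=0.19)
        areas = {c: cell_geometry(mesh, c).area for c in mesh.cells}
        k_only = MechanicalParams(K=1.0, Lambda=0.0, Gamma=1e-9)
        downhill = {0: areas[0] - 0.3, 1: areas[1] - 0.3,
                    2: areas[2] + 0.3, 3: areas[3] + 0.3}
        uphill = {0: areas[0] + 0.3, 1: areas[1] + 0.3,
                  2: areas[2] - 0.3, 3: areas[3] - 0.3}

        for targets, expect_apply in [(downhill, True), (uphill, False)]:
            m_gated = pinwheel(edge_len=0.19)
            m_forced = pinwheel(edge_len=0.19)
            e0 = total_energy(m_forced, targets, k_only)
            assert apply_T1(m_forced, (0, 1), PARAMS)  # ungated reference
            e1 = total_energy(m_forced, targets, k_only)
            assert (e1 < e0) is expect_apply
            applied = apply_T1(m_gated, (0, 1), PARAMS, targets=targets, mech=k_only)
            assert applied is expect_apply
            if not applied:
                # rejected swap leaves the mesh untouched
                assert m_gated.cells == pinwheel(edge_len=0.19).cells
                assert np.array_equal(m_gated.vertices, pinwheel(edge_len=0.19).vertices)


class TestT2:
    def test_removes_small_triangle(self):
        mesh, center = shrunken_center()
        # shrink to a triangle first via T1s, then collapse; here build the
        # triangle directly: replace central hexagon by one of its triangles
        # -> use sweep-based path in TestSweep; this test uses a hand fixture.
        verts = [[0.0, 0.1], [-0.087, -0.05], [0.087, -0.05],       # small triangle
                 [0.0, 1.0], [-0.87, -0.5], [0.87, -0.5]]           # outer ring
        cells = {
            0: [0, 1, 2],            # CCW small triangle
            1: [0, 3, 4, 1],         # left neighbour
            2: [1, 4, 5, 2],         # bottom neighbour
            3: [2, 5, 3, 0],         # right neighbour
        }
        mesh = TissueMesh(verts, cells)
        validate_mesh(mesh)
        nv_used = len(mesh.used_vertices())
        log = EventLog()
        assert apply_T2(mesh, 0, TopologyParams(l_T1=0.01, l_new=0.02, A_T2=0.1),
                        log=log)
        assert mesh.n_cells == 3
        assert all(len(l) == 3 for l in mesh.cells.values())  # each lost a side
        assert len(mesh.used_vertices()) == nv_used - 2       # 3 vertices -> 1
        validate_mesh(mesh)
        assert log.count("T2") == 1

    def test_large_triangle_not_removed(self):
        verts = [[0, 0], [1, 0], [0.5, 1]]
        mesh = TissueMesh(verts, {0: [0, 1, 2]})
        assert not apply_T2(mesh, 0, TopologyParams(l_T1=0.01, l_new=0.02, A_T2=0.1))

    def test_many_sided_cell_not_removed(self):
        mesh = build_hexagonal_lattice(1, 0.01)  # tiny hexagon, area << A_T2
        assert not apply_T2(mesh, 0, PARAMS)
        assert mesh.n_cells == 1


class TestSweep:
    def test_identity_on_clean_mesh(self):
        mesh = build_hexagonal_lattice(7, UNIT_SIDE)
        before = {cid: list(l) for cid, l in mesh.cells.items()}
        n, skipped = sweep_topology(mesh, TopologyParams(l_T1=0.05, l_new=0.06, A_T2=0.02))
        assert n == 0 and not skipped
        assert mesh.cells == before

    def test_single_short_edge_gives_one_t1(self):
        mesh = pinwheel(edge_len=0.02)
        log = EventLog()
        n, _ = sweep_topology(mesh, TopologyParams(l_T1=0.05, l_new=0.06, A_T2=1e-6),
                              log=log)
        assert n == 1 and log.count("T1") == 1
        validate_mesh(mesh)

    def test_shrunken_cell_t1s_then_t2(self):
        """A cell contracted far below the area threshold loses sides through
        T1s until it is a triangle, then is removed by a T2."""
        from epivertex.topology import untangle_collapsed_edges

        mesh, center = shrunken_center(scale=0.04)
        log = EventLog()
        params = TopologyParams(l_T1=0.06, l_new=0.065, A_T2=0.02)
        n, _ = sweep_topology(mesh, params, log=log)
        untangle_collapsed_edges(mesh, params, l_check=2 * params.l_new)
        assert center not in mesh.cells
        assert log.count("T1") >= 1
        assert log.count("T2") >= 1
        assert mesh.n_cells == 15
        validate_mesh(mesh)

    def test_deterministic(self):
        m1, _ = shrunken_center(scale=0.04)
        m2, _ = shrunken_center(scale=0.04)
        params = TopologyParams(l_T1=0.06, l_new=0.065, A_T2=0.02)
        sweep_topology(m1, params)
        sweep_topology(m2, params)
        assert m1.cells == m2.cells
        assert np.array_equal(m1.vertices, m2.vertices)


class TestEventLog:
    def test_times_must_be_nondecreasing(self):
        log = EventLog()
        log.append(1.0, "T1", (1, 2, 3, 4))
        log.append(1.0, "T2", (5,))
        with pytest.raises(ValueError):
            log.append(0.5, "division", (1, 2, 3))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            EventLog().append(0.0, "T3", (1,))

    def test_csv_roundtrip_columns(self, tmp_path):
        import pandas as pd
        log = EventLog()
        log.append(1.0, "division", (0, 1, 2), parent_area=1.5)
        log.append(2.0, "T1", (1, 2, 3, 4), edge="7-9")
        path = tmp_path / "events.csv"
        log.write_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "kind", "cell_ids", "details"]
        assert df.kind.tolist() == ["division", "T1"]
        assert df.cell_ids.tolist() == ["0;1;2", "1;2;3;4"]
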