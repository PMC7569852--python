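"""Split-operator driver: conservation, eigenmode decay, diagnostics."""

import numpy as np
import pytest

import rdfem
from rdfem.errors import GeometryError, ParameterError, StateError

PURE_DIFFUSION = rdfem.ReactionParams.pure_diffusion()


def open_rect(h, w, s):
    mesh = rdfem.build_mesh(rdfem.RasterMask(np.ones((h, w), bool)), s)
    D, S = rdfem.assemble(mesh)
    return mesh, D, S


class TestInitializeFields:
    def test_full_domain_zone(self, rect_mesh):
        mask = np.ones((3, 5), bool)
        N0, P0 = rdfem.initialize_fields(rect_mesh, mask)
        assert np.all(N0 == 1.0) and np.all(P0 == 1.0)

    def test_bottom_strip_selects_bottom_node_row(self):
        """One-pixel bottom strip on a 10x10 open square at s=1: exactly the
        11 nodes with y=0."""
        mask = rdfem.RasterMask(np.ones((10, 10), bool))
        mesh = rdfem.build_mesh(mask, 1)
        zone = rdfem.starting_zone(mask)  # default: bottom strip, 1 px
        N0, _ = rdfem.initialize_fields(mesh, zone)
        assert N0.sum() == 11
        assert np.all(mesh.nodes[N0 > 0, 1] == 0.0)

    def test_callable_predicate(self, rect_mesh):
        N0, _ = rdfem.initialize_fields(rect_mesh, lambda x, y: x < 1.0)
        assert np.all((rect_mesh.nodes[:, 0] < 1.0) == (N0 > 0))

    def test_empty_zone_rejected(self, rect_mesh):
        with pytest.raises(GeometryError):
            rdfem.initialize_fields(rect_mesh, np.zeros((3, 5), bool))


class TestDiffusionStep:
    def test_constant_field_is_steady_state(self, rect_matrices):
        D, S = rect_matrices
        A = rdfem.system_matrix(D, S, 0.01)
        c = 0.7 * np.ones(D.dimension)
        out, report = rdfem.diffusion_step(A, D, c)
        np.testing.assert_array_equal(out, c)
        assert report.iterations == 0  # warm start is already exact

    def test_mass_conserved_single_step(self, maze_matrices):
        D, S = maze_matrices
        A = rdfem.system_matrix(D, S, 0.01)
        rng = np.random.default_rng(0)
        field = rng.uniform(0, 2, D.dimension)
        settings = rdfem.SolverSettings(rtol=1e-13, max_iter=5000)
        out, _ = rdfem.diffusion_step(A, D, field, settings)
        ones = np.ones(D.dimension)
        before = ones @ (D.csr @ field)
        after = ones @ (D.csr @ out)
        assert after == pytest.approx(before, rel=1e-10)

    def test_cosine_eigenmode_decay_rate(self):
        """Lowest Neumann mode cos(πx/L) decays by 1/(1+τλ1) per implicit
        step, λ1=(π/L)²; within 2% at 64 cells along L and improving with
        refinement."""
        L, tau = 16, 0.05
        lam1 = (np.pi / L) ** 2
        errors = []
        for s in (4, 8):  # 64 and 128 cells along L
            mesh, D, S = open_rect(2, L, s)
            A = rdfem.system_matrix(D, S, tau)
            field = np.cos(np.pi * mesh.nodes[:, 0] / L) + 1.0  # keep nonnegative
            settings = rdfem.SolverSettings(rtol=1e-13, max_iter=10000)
            lumped = D.csr @ np.ones(D.dimension)
            prev = field
            rates = []
            for _ in range(3):
                nxt, _ = rdfem.diffusion_step(A, D, prev, settings)
                mean_prev = (lumped @ prev) / lumped.sum()
                mean_next = (lumped @ nxt) / lumped.sum()
                amp_prev = np.max(np.abs(prev - mean_prev))
                amp_next = np.max(np.abs(nxt - mean_next))
                rates.append(amp_next / amp_prev)
                prev = nxt
            lam_eff = (1.0 / rates[-1] - 1.0) / tau
            errors.append(abs(lam_eff - lam1) / lam1)
        assert errors[0] < 0.02
        assert errors[1] < errors[0]


class TestRun:
    def test_zero_state_stays_zero(self, rect_mesh, rect_matrices):
        D, S = rect_matrices
        cfg = rdfem.SimulationConfig(n_steps=50, snapshot_stride=10)
        z = np.zeros(rect_mesh.n_nodes)
        res = rdfem.run(rect_mesh, D, S, cfg, z, z)
        assert all(np.all(s.N == 0) and np.all(s.P == 0) for s in res.snapshots)

    def test_pure_diffusion_mass_conservation(self, maze_mesh, maze_matrices):
        D, S = maze_matrices
        cfg = rdfem.SimulationConfig(
            n_steps=200, params=PURE_DIFFUSION,
            solver=rdfem.SolverSettings(rtol=1e-12, max_iter=20000),
            snapshot_stride=50)
        mask = rdfem.generate_maze(5, 5, 3, 1, seed=3)
        # bottom corridor row (the 1-px default strip would sit on the wall)
        zone = rdfem.starting_zone(mask, rdfem.ZoneSpec(
            rows=(mask.height - 4, mask.height), cols=(0, mask.width)))
        N0, P0 = rdfem.initialize_fields(maze_mesh, zone)
        # positive baseline keeps the state clear of the clamp, which only
        # fires on (unphysical) negative undershoots and would add mass
        N0, P0 = N0 + 0.5, P0 + 0.5
        res = rdfem.run(maze_mesh, D, S, cfg, N0, P0)
        masses = np.array([t.mass_n for t in res.traces])
        assert np.max(np.abs(masses - masses[0])) <= 1e-9 * masses[0]

    def test_operator_orders_agree_at_order_tau(self, rect_mesh, rect_matrices):
        D, S = rect_matrices
        N0 = np.zeros(rect_mesh.n_nodes); N0[rect_mesh.nodes[:, 1] == 0] = 1.0
        results = {}
        for order in ("reaction_first", "diffusion_first"):
            cfg = rdfem.SimulationConfig(n_steps=100, order=order,
                                         snapshot_stride=100)
            results[order] = rdfem.run(rect_mesh, D, S, cfg, N0, N0).final.N
        diff = np.max(np.abs(results["reaction_first"] - results["diffusion_first"]))
        assert 0 < diff < 0.05  # the variants differ, but only at O(τ)

    def test_degenerate_mesh_rejected(self, rect_matrices):
        D, S = rect_matrices
        tiny = rdfem.meshing.TriMesh(np.zeros((2, 2)), np.zeros((0, 3), dtype=int),
                                     np.zeros((0, 2), dtype=int))
        with pytest.raises(GeometryError):
            rdfem.run(tiny, D, S, rdfem.SimulationConfig(n_steps=1),
                      np.zeros(2), np.zeros(2))

    def test_negative_initial_state_rejected(self, rect_mesh, rect_matrices):
        D, S = rect_matrices
        bad = -np.ones(rect_mesh.n_nodes)
        with pytest.raises(StateError):
            rdfem.run(rect_mesh, D, S, rdfem.SimulationConfig(n_steps=1), bad, bad)

    def test_determinism(self, rect_mesh, rect_matrices):
        D, S = rect_matrices
        N0 = np.zeros(rect_mesh.n_nodes); N0[0] = 1.0
        cfg = rdfem.SimulationConfig(n_steps=30, snapshot_stride=30)
        a = rdfem.run(rect_mesh, D, S, cfg, N0, N0)
        b = rdfem.run(rect_mesh, D, S, cfg, N0, N0)
        np.testing.assert_array_equal(a.final.N, b.final.N)
        np.testing.assert_array_equal(a.final.P, b.final.P)


class TestConditionNumberEstimate:
    def test_identity_is_exactly_one(self):
        assert rdfem.estimate_condition_number(np.eye(10), n_probes=5, seed=0) == 1.0

    def test_diag_estimator_bounded_by_true_kappa(self):
        kappa = rdfem.estimate_condition_number(np.diag([1.0, 4.0]),
                                                n_probes=10_000, seed=1)
        assert 3.5 < kappa <= 4.0 + 1e-9

    def test_seeded_determinism(self, rect_matrices):
        D, S = rect_matrices
        A = rdfem.system_matrix(D, S, 0.01)
        a = rdfem.estimate_condition_number(A, n_probes=20, seed=7)
        b = rdfem.estimate_condition_number(A, n_probes=20, seed=7)
        assert a == b

    def test_never_exceeds_dense_oracle(self, rect_matrices):
        D, S = rect_matrices
        A = rdfem.system_matrix(D, S, 0.01)
        assert A.dimension <= 200
        true_kappa = np.linalg.cond(A.matrix.toarray(), 2)
        est = rdfem.estimate_condition_number(A, n_probes=200, seed=2)
        assert est <= true_kappa * (1 + 1e-6)

    def test_bad_probe_count(self):
        with pytest.raises(ParameterError):
            rdfem.estimate_condition_number(np.eye(3), n_probes=0)


class TestArrivalTimeMap:
    def test_seed_nodes_arrive_at_step_zero(self, rect_mesh):
        snaps = [rdfem.Snapshot(0, np.array([1.0, 0.0]), np.zeros(2)),
                 rdfem.Snapshot(10, np.array([1.0, 0.5]), np.zeros(2))]
        arr = rdfem.arrival_time_map(snaps, 0.1)
        assert arr[0] == 0 and arr[1] == 10

    def test_unreached_nodes_are_inf(self):
        snaps = [rdfem.Snapshot(0, np.zeros(3), np.zeros(3))]
        assert np.all(np.isinf(rdfem.arrival_time_map(snaps, 0.1)))

    def test_corridor_arrival_monotone_with_distance(self):
        """In a straight corridor the wave front sweeps left to right, so
        first-passage times are non-decreasing in x."""
        mask = rdfem.RasterMask(np.ones((3, 24), bool))
        mesh = rdfem.build_mesh(mask, 2)
        D, S = rdfem.assemble(mesh)
        zone = np.zeros((3, 24), bool); zone[:, :2] = True
        N0, P0 = rdfem.initialize_fields(mesh, zone)
        cfg = rdfem.SimulationConfig(n_steps=1500, snapshot_stride=25)
        res = rdfem.run(mesh, D, S, cfg, N0, P0)
        arr = rdfem.arrival_time_map(res.snapshots, 0.1)
        xs = np.unique(mesh.nodes[:, 0])
        col_arrival = [np.median(arr[mesh.nodes[:, 0] == x]) for x in xs]
        finite = [a for a in col_arrival if np.isfinite(a)]
        assert len(finite) > 10  # the wave actually progressed
        assert all(b >= a for a, b in zip(finite, finite[1:]))
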