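"""Discrete Helfrich mechanics: geometry, energy, forces, relaxation."""

import numpy as np
import pytest

from spinedyn import membrane as mb
from spinedyn import _kernels as _kern


def fd_gradient(mesh, params, h=1e-6):
    g = np.zeros_like(mesh.vertices)
    for k in range(mesh.n):
        for c in range(2):
            mp, mm = mesh.copy(), mesh.copy()
            mp.vertices[k, c] += h
            mm.vertices[k, c] -= h
            g[k, c] = (mb.membrane_energy(mp, params)
                       - mb.membrane_energy(mm, params)) / (2 * h)
    return -g


class TestGeometry:
    def test_unit_square_area_and_length(self, unit_square):
        assert mb.enclosed_area(unit_square) == pytest.approx(1.0)
        assert mb.boundary_length(unit_square) == pytest.approx(4.0)

    def test_reversed_square_area_positive(self, unit_square):
        rev = mb.MembraneMesh(unit_square.vertices[::-1].copy(),
                              unit_square.roles.copy(), np.inf, -np.inf)
        assert mb.enclosed_area(rev) == pytest.approx(1.0)

    def test_regular_polygon_limits(self):
        m = mb.circle_mesh(1.0, 1000)
        assert mb.enclosed_area(m) == pytest.approx(np.pi, abs=1e-4)
        n = 64
        m = mb.circle_mesh(1.0, n)
        assert mb.boundary_length(m) == pytest.approx(
            n * 2 * np.sin(np.pi / n))

    def test_too_few_vertices_invalid(self):
        m = mb.MembraneMesh(np.zeros((2, 2)), np.zeros(2, dtype=np.int8),
                            np.inf, -np.inf)
        with pytest.raises(mb.InvalidMeshError):
            mb.enclosed_area(m)

    def test_coincident_vertices_invalid(self):
        verts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        m = mb.MembraneMesh(verts, np.zeros(4, dtype=np.int8),
                            np.inf, -np.inf)
        with pytest.raises(mb.InvalidMeshError):
            mb.boundary_length(m)

    @pytest.mark.parametrize("radius, expect", [(2.0, 0.5), (0.5, 2.0)])
    def test_circle_curvature(self, radius, expect):
        m = mb.circle_mesh(radius, 360)
        kappa = mb.discrete_curvature(m)
        assert np.allclose(kappa, expect, atol=1e-3)

    def test_straight_line_zero_curvature(self):
        verts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0],
                          [2.0, 1.0], [0.0, 1.0]])
        m = mb.MembraneMesh(verts, np.zeros(5, dtype=np.int8),
                            np.inf, -np.inf)
        assert mb.discrete_curvature(m)[1] == pytest.approx(0.0, abs=1e-12)


class TestEnergyForce:
    def test_zero_params_zero_energy(self, unit_square):
        p = mb.MechanicalParams(P=0.0, tau=0.0, kappa=0.0)
        assert mb.membrane_energy(unit_square, p) == 0.0
        assert np.all(mb.membrane_force(unit_square, p) == 0.0)

    def test_circle_energy_closed_form(self):
        p = mb.MechanicalParams(P=0.4, tau=1.5, kappa=0.04)
        r = 0.7
        m = mb.circle_mesh(r, 2000)
        expect = (p.P * np.pi * r ** 2 + p.tau * 2 * np.pi * r
                  + 4 * np.pi * p.kappa / r)
        assert mb.membrane_energy(m, p) == pytest.approx(expect, rel=1e-2)

    def test_bending_term_linear_in_kappa(self, blob_factory):
        m = blob_factory(np.random.default_rng(1))
        p0 = mb.MechanicalParams(P=0.0, tau=0.0, kappa=0.03)
        p2 = mb.MechanicalParams(P=0.0, tau=0.0, kappa=0.06)
        assert mb.membrane_energy(m, p2) == pytest.approx(
            2.0 * mb.membrane_energy(m, p0), rel=1e-12)

    def test_force_matches_finite_difference_on_random_meshes(
            self, blob_factory):
        rng = np.random.default_rng(7)
        p = mb.MechanicalParams()
        worst = 0.0
        for _ in range(100):
            m = blob_factory(rng, n=24)
            f = mb.membrane_force(m, p)
            g = fd_gradient(m, p)
            worst = max(worst,
                        np.abs(f - g).max() / max(np.abs(g).max(), 1e-12))
        assert worst < 1e-4

    def test_jitted_force_matches_reference(self, blob_factory):
        m = blob_factory(np.random.default_rng(3))
        p = mb.MechanicalParams()
        f_ref = mb.membrane_force(m, p)
        f_jit = _kern.mem_force(m.vertices, p.P, p.tau, p.kappa)
        assert np.abs(f_ref - f_jit).max() < 1e-12

    def test_circle_equilibrium_force_vanishes(self):
        p = mb.MechanicalParams()
        r_star = mb.equilibrium_radius(p)
        assert p.P * r_star ** 3 + p.tau * r_star ** 2 == pytest.approx(
            2 * p.kappa, rel=1e-10)
        m = mb.circle_mesh(r_star, 512)
        f = mb.membrane_force(m, p)
        assert np.abs(f).max() < 1e-4

    def test_translation_invariance(self, blob_factory):
        m = blob_factory(np.random.default_rng(5))
        p = mb.MechanicalParams()
        f0 = mb.membrane_force(m, p)
        shifted = m.copy()
        shifted.vertices += np.array([1.3, -0.7])
        assert np.allclose(mb.membrane_force(shifted, p), f0, atol=1e-9)

    def test_rotation_equivariance(self, blob_factory):
        m = blob_factory(np.random.default_rng(6))
        p = mb.MechanicalParams()
        f0 = mb.membrane_force(m, p)
        a = 0.7
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        rot = m.copy()
        rot.vertices = m.vertices @ R.T
        assert np.allclose(mb.membrane_force(rot, p), f0 @ R.T, atol=1e-9)


class TestSteppingRemeshing:
    def test_zero_force_identity(self, params):
        m = mb.circle_mesh(0.3, 40)
        out = mb.step_vertices(m, np.zeros_like(m.vertices), params,
                               do_remesh=False)
        assert np.array_equal(out.vertices, m.vertices)

    def test_euler_step_displacement(self):
        p = mb.MechanicalParams(zeta=1.0, dt=0.01, d_max=0.1)
        m = mb.circle_mesh(0.3, 40)
        force = np.zeros_like(m.vertices)
        force[5, 0] = 1.0
        out = mb.step_vertices(m, force, p, do_remesh=False)
        assert out.vertices[5, 0] - m.vertices[5, 0] == pytest.approx(0.01)

    def test_pinned_vertex_does_not_move(self, params):
        m = mb.stadium_mesh()
        force = np.ones_like(m.vertices)
        out = mb.step_vertices(m, force, params, do_remesh=False)
        pinned = ~m.free_mask
        assert np.array_equal(out.vertices[pinned], m.vertices[pinned])

    def test_oversized_step_raises(self):
        p = mb.MechanicalParams(zeta=1.0, dt=1.0)
        m = mb.circle_mesh(0.3, 40)
        force = np.full_like(m.vertices, 10.0)
        with pytest.raises(mb.TimeStepError):
            mb.step_vertices(m, force, p)

    def test_remesh_noop_on_compliant_mesh(self, params):
        m = mb.circle_mesh(0.3, 48)      # edge ~0.039
        out = mb.remesh(m, params)
        assert np.array_equal(out.vertices, m.vertices)

    def test_remesh_merges_close_free_pair(self, params):
        m = mb.circle_mesh(0.3, 48)
        m.vertices[1] = m.vertices[0] + np.array([0.01, 0.0])
        out = mb.remesh(m, params)
        _, el = mb._edge_vectors(out.vertices)
        assert el.min() >= params.d_min
        assert el.max() <= params.d_max + 1e-12

    def test_remesh_splits_long_edge(self, params):
        m = mb.circle_mesh(0.3, 48)
        m2 = mb.MembraneMesh(np.delete(m.vertices, 1, axis=0),
                             np.delete(m.roles, 1), m.h_psd, m.h_neck)
        out = mb.remesh(m2, params)
        _, el = mb._edge_vectors(out.vertices)
        assert el.max() <= params.d_max + 1e-12

    def test_remesh_keeps_pinned_vertex(self, params):
        m = mb.stadium_mesh()
        psd_first = m.psd_indices[0]
        neighbour = psd_first - 1
        m.vertices[neighbour] = m.vertices[psd_first] + np.array([0.0, -0.005])
        out = mb.remesh(m, params)
        assert len(out.psd_indices) == len(m.psd_indices)
        _, el = mb._edge_vectors(out.vertices)
        assert el.min() >= params.d_min

    def test_remesh_idempotent(self, params):
        rng = np.random.default_rng(11)
        m = mb.circle_mesh(0.3, 60)
        m.vertices += rng.normal(0, 0.004, m.vertices.shape)
        once = mb.remesh(m, params)
        twice = mb.remesh(once, params)
        assert np.array_equal(once.vertices, twice.vertices)

    def test_energy_descends_under_zero_actin_steps(self, params):
        m = mb.circle_mesh(0.14, 24)
        e_prev = mb.membrane_energy(m, params)
        p_small = mb.MechanicalParams(dt=5e-4)
        for _ in range(50):
            f = mb.membrane_force(m, p_small)
            m = mb.step_vertices(m, f, p_small, do_remesh=False)
            e = mb.membrane_energy(m, p_small)
            assert e <= e_prev + 1e-10
            e_prev = e


class TestRelaxation:
    def test_free_circle_relaxes_to_equilibrium_radius(self, params):
        r_star = mb.equilibrium_radius(params)
        m = mb.relax_to_rest(mb.circle_mesh(1.3 * r_star, 24), params)
        radius = np.hypot(*m.vertices.T).mean()
        assert radius == pytest.approx(r_star, rel=0.01)

    def test_rest_shape_is_fixed_point(self, params):
        rest = mb.relax_to_rest(mb.stadium_mesh(), params)
        again = mb.relax_to_rest(rest, params)
        assert mb.enclosed_area(again) == pytest.approx(
            mb.enclosed_area(rest), abs=1e-4)

    def test_perturbed_rest_returns(self, params):
        rest = mb.relax_to_rest(mb.stadium_mesh(), params)
        pert = rest.copy()
        rng = np.random.default_rng(2)
        free = pert.free_mask
        pert.vertices[free] += rng.normal(0, 0.003, (int(free.sum()), 2))
        back = mb.relax_to_rest(pert, params)
        assert mb.enclosed_area(back) == pytest.approx(
            mb.enclosed_area(rest), abs=2e-3)


class TestIO:
    def test_csv_roundtrip(self, tmp_path, params):
        m = mb.stadium_mesh()
        path = tmp_path / "mesh.csv"
        mb.write_mesh_csv(m, path)
        back = mb.read_mesh_csv(path)
        assert np.allclose(back.vertices, m.vertices)
        assert np.array_equal(back.roles, m.roles)
        assert back.h_psd == pytest.approx(m.h_psd)
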