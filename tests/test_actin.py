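"""Stochastic focus dynamics: rates, events, forces, bookkeeping."""

import numpy as np
import pytest

from spinedyn import actin as ac
from spinedyn import membrane as mb


@pytest.fixture()
def rates():
    return ac.ActinRates()


@pytest.fixture()
def focus():
    return ac.Focus(id=0, X_n=(0.0, 0.4), n_minus_capped=2,
                    n_minus_uncapped=1)


class TestBranchingRate:
    def test_zero_force_single_filament(self, rates):
        assert ac.branching_rate(1, 0.0, rates) == pytest.approx(
            rates.poly_coeff)

    def test_decreases_with_force_and_barbed_ends(self, rates):
        forces = np.linspace(0, 20, 15)
        vals = [ac.branching_rate(3, F, rates) for F in forces]
        assert np.all(np.diff(vals) < 0)
        # large-B limit: the per-filament rate vanishes as 1/B
        vals = [ac.branching_rate(int(b), 5.0, rates)
                for b in (1, 10, 100, 10_000)]
        assert vals[-1] < 1e-2 * max(vals)

    def test_extinct_focus_rejected(self, rates):
        with pytest.raises(ac.ExtinctFocusError):
            ac.branching_rate(0, 1.0, rates)

    def test_nonfeedback_rate_is_constant(self, rates):
        ref = ac.branching_rate(1, 0.0, rates, feedback=False)
        for B, F in [(1, 0.0), (7, 3.0), (50, 100.0)]:
            assert ac.branching_rate(B, F, rates, feedback=False) == ref
        expect = (rates.poly_coeff / ac.NONFEEDBACK_B
                  * np.exp(-ac.NONFEEDBACK_F_PN * rates.delta
                           / (rates.kBT * ac.NONFEEDBACK_B)))
        assert ref == pytest.approx(expect)


class TestStepFocus:
    def test_no_rates_no_change(self, focus):
        quiet = ac.ActinRates(gamma_cap=0, gamma_uncap=0, gamma_sever=0,
                              phi=0)
        rng = np.random.default_rng(0)
        out, events, counts = ac.step_focus(focus, 0.0, quiet, rng)
        assert out == focus
        assert events == focus.B == 3
        assert all(v == 0 for v in counts.values())

    def test_certain_capping_extinguishes(self, focus):
        certain = ac.ActinRates(gamma_cap=100.0, gamma_uncap=0,
                                gamma_sever=0, phi=0, dt=0.01)
        rng = np.random.default_rng(0)
        out, events, counts = ac.step_focus(focus, 0.0, certain, rng)
        assert out.extinct
        assert counts["cap"] == 3
        assert events == 3

    def test_extinct_focus_rejected(self, rates):
        dead = ac.Focus(id=0, X_n=(0, 0), n_minus_capped=0,
                        n_minus_uncapped=0)
        with pytest.raises(ac.ExtinctFocusError):
            ac.step_focus(dead, 0.0, rates, np.random.default_rng(0))

    def test_overlarge_probability_rejected(self, focus):
        bad = ac.ActinRates(gamma_cap=60.0, gamma_uncap=60.0, dt=0.01)
        with pytest.raises(ValueError):
            ac.step_focus(focus, 0.0, bad, np.random.default_rng(0))

    def test_bookkeeping_conserves_barbed_ends(self, rates):
        rng = np.random.default_rng(42)
        f = ac.Focus(id=0, X_n=(0, 0.4), n_minus_capped=5,
                     n_minus_uncapped=5)
        for _ in range(500):
            if f.extinct:
                break
            before = f.B
            f, _, c = ac.step_focus(f, 1.0, rates, rng)
            assert f.B - before == c["branch"] - c["cap"] - c["sever"]
            assert f.n_minus_capped >= 0 and f.n_minus_uncapped >= 0

    def test_pure_branching_matches_birth_process_mean(self):
        # only branching, zero force: the per-filament rate is
        # poly_coeff/B, so the total branch rate is a constant poly_coeff
        # and E[B_k] = 1 + k*poly_coeff*dt
        r = 2.0
        dt = 0.01
        k = 50
        only_branch = ac.ActinRates(gamma_cap=0, gamma_uncap=0,
                                    gamma_sever=0, phi=1.0, k_on=1.0,
                                    delta=1.0, a=r, dt=dt)
        rng = np.random.default_rng(123)
        n_rep = 10_000
        finals = np.empty(n_rep)
        for i in range(n_rep):
            f = ac.Focus(id=0, X_n=(0, 0), n_minus_capped=1)
            for _ in range(k):
                f, _, _ = ac.step_focus(f, 0.0, only_branch, rng)
            finals[i] = f.B
        expect = 1 + k * r * dt
        se = finals.std() / np.sqrt(n_rep)
        assert abs(finals.mean() - expect) < 3 * se

    def test_extinction_time_matches_geometric_decay(self):
        # pure capping: per-step survival of a single filament is 1 - p
        p = 0.05
        cap_only = ac.ActinRates(gamma_cap=5.0, gamma_uncap=0,
                                 gamma_sever=0, phi=0, dt=0.01)
        rng = np.random.default_rng(7)
        lifetimes = []
        for _ in range(10_000):
            f = ac.Focus(id=0, X_n=(0, 0), n_minus_capped=1)
            steps = 0
            while not f.extinct:
                f, _, _ = ac.step_focus(f, 0.0, cap_only, rng)
                steps += 1
            lifetimes.append(steps)
        lifetimes = np.asarray(lifetimes)
        expect_mean = 1.0 / p
        se = lifetimes.std() / np.sqrt(len(lifetimes))
        assert abs(lifetimes.mean() - expect_mean) < 3 * se

    def test_seed_determinism(self, rates, focus):
        def run(seed):
            rng = np.random.default_rng(seed)
            f = focus
            history = []
            for _ in range(200):
                if f.extinct:
                    break
                f, _, c = ac.step_focus(f, 2.0, rates, rng)
                history.append((f.n_minus_capped, f.n_minus_uncapped,
                                tuple(sorted(c.items()))))
            return history

        assert run(99) == run(99)


class TestNucleation:
    def test_zero_rate_never_nucleates(self):
        mesh = mb.stadium_mesh()
        quiet = ac.ActinRates(gamma_f=0.0)
        rng = np.random.default_rng(0)
        assert all(ac.maybe_nucleate(mesh, quiet, rng) is None
                   for _ in range(200))

    def test_certain_rate_nucleates_inside(self):
        from shapely.geometry import Point, Polygon

        mesh = mb.stadium_mesh()
        hot = ac.ActinRates(gamma_f=100.0, dt=0.01)
        rng = np.random.default_rng(1)
        poly = Polygon(mesh.vertices)
        for i in range(50):
            f = ac.maybe_nucleate(mesh, hot, rng, focus_id=i)
            assert f is not None
            assert poly.contains(Point(f.X_n))
            assert f.n_minus_capped == 1 and f.n_minus_uncapped == 0

    def test_nucleation_frequency_binomial(self):
        mesh = mb.stadium_mesh()
        rates = ac.ActinRates(gamma_f=30.0, dt=0.01)     # p = 0.3
        rng = np.random.default_rng(5)
        n = 100_000
        hits = sum(ac.maybe_nucleate(mesh, rates, rng) is not None
                   for _ in range(n))
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(hits / n - 0.3) < 3 * se


class TestActinForce:
    def test_extinct_focus_zero_field(self):
        mesh = mb.circle_mesh(0.5, 32)
        kp = ac.KernelParams()
        dead = ac.Focus(id=0, X_n=(0, 0), n_minus_capped=0)
        assert np.all(ac.actin_force(dead, mesh, kp) == 0.0)

    def test_kernel_peak_magnitude(self):
        kp = ac.KernelParams(amplitude=0.5, sigma=0.2)
        mesh = mb.MembraneMesh(
            np.array([[1e-9, 0.0], [1.0, 0.0], [1.0, 1.0]]),
            np.zeros(3, dtype=np.int8), np.inf, -np.inf)
        f = ac.actin_force(ac.Focus(id=0, X_n=(0.0, 0.0)), mesh, kp)
        peak = kp.amplitude / (kp.sigma * np.sqrt(2 * np.pi))
        assert np.hypot(*f[0]) == pytest.approx(peak, rel=1e-6)

    def test_gaussian_falloff_at_sigma(self):
        kp = ac.KernelParams()
        mesh = mb.MembraneMesh(
            np.array([[1e-9, 0.0], [kp.sigma, 0.0], [1.0, 1.0]]),
            np.zeros(3, dtype=np.int8), np.inf, -np.inf)
        f = ac.actin_force(ac.Focus(id=0, X_n=(0.0, 0.0)), mesh, kp)
        ratio = np.hypot(*f[1]) / np.hypot(*f[0])
        assert ratio == pytest.approx(np.exp(-0.5), rel=1e-6)

    def test_vertex_on_nucleation_point_contributes_zero(self):
        kp = ac.KernelParams()
        mesh = mb.MembraneMesh(
            np.array([[0.0, 0.0], [0.5, 0.0], [0.5, 0.5]]),
            np.zeros(3, dtype=np.int8), np.inf, -np.inf)
        f = ac.actin_force(ac.Focus(id=0, X_n=(0.0, 0.0)), mesh, kp)
        assert np.all(f[0] == 0.0)

    def test_field_scales_with_barbed_ends(self):
        kp = ac.KernelParams()
        mesh = mb.circle_mesh(0.3, 16)
        f1 = ac.actin_force(
            ac.Focus(id=0, X_n=(0.05, 0.0), n_minus_capped=1), mesh, kp)
        f4 = ac.actin_force(
            ac.Focus(id=0, X_n=(0.05, 0.0), n_minus_capped=4), mesh, kp)
        assert np.allclose(f4, 4.0 * f1)


class TestLocalMembraneForce:
    def test_zero_field_gives_zero(self):
        mesh = mb.circle_mesh(0.3, 16)
        kp = ac.KernelParams()
        f = ac.Focus(id=0, X_n=(0.0, 0.0))
        assert ac.local_membrane_force(
            f, mesh, np.zeros_like(mesh.vertices), kp) == 0.0

    def test_single_dominant_vertex_norm(self):
        kp = ac.KernelParams(sigma=0.01)
        mesh = mb.MembraneMesh(
            np.array([[0.0, 0.0], [5.0, 0.0], [5.0, 5.0]]),
            np.zeros(3, dtype=np.int8), np.inf, -np.inf)
        forces = np.array([[3.0, 4.0], [100.0, 100.0], [-50.0, 0.0]])
        f = ac.Focus(id=0, X_n=(0.0, 0.0))
        assert ac.local_membrane_force(f, mesh, forces, kp) == pytest.approx(
            5.0, rel=1e-6)

    def test_opposing_forces_cancel_in_net_mode(self):
        kp = ac.KernelParams(sigma=0.5)
        mesh = mb.MembraneMesh(
            np.array([[0.1, 0.0], [-0.1, 0.0], [0.0, 50.0]]),
            np.zeros(3, dtype=np.int8), np.inf, -np.inf)
        forces = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 0.0]])
        f = ac.Focus(id=0, X_n=(0.0, 0.0))
        # static kernel centre at X_n: symmetric weights, net cancels
        assert ac.local_membrane_force(
            f, mesh, forces, kp, mode="net",
            X_c=f.X_n) == pytest.approx(0.0, abs=1e-12)
        # the magnitude reading reports the (non-cancelling) load
        assert ac.local_membrane_force(
            f, mesh, forces, kp, X_c=f.X_n) == pytest.approx(1.0, rel=1e-6)

    def test_far_focus_zero(self):
        kp = ac.KernelParams(sigma=0.1)
        mesh = mb.circle_mesh(0.3, 16)
        far = ac.Focus(id=0, X_n=(1e6, 1e6))
        forces = np.ones_like(mesh.vertices)
        assert ac.local_membrane_force(far, mesh, forces, kp) == 0.0
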