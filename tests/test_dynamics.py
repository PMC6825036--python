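import numpy as np
import pytest

from lvmodes.constitutive import ActiveParams, PassiveParams
from lvmodes.dynamics import (KPA_PER_MMHG, CirculationParams, LVModel,
                              valve_flows)
from lvmodes.modes import standard_basis


@pytest.fixture(scope="module")
def model():
    from lvmodes.geometry import make_fixture_geometry
    return LVModel(make_fixture_geometry("axisymmetric"), standard_basis(8),
                   n_mu=3, n_nu=11, n_phi=12)


class TestAssembly:
    def test_reference_state_is_stress_free(self, model):
        co = model.assemble(np.zeros(8), t=-1.0)  # no activation
        assert np.max(np.abs(co.kappa)) < 1e-10

    def test_viscous_alpha_symmetric_psd(self, model, rng):
        # with k_av = 0 only the viscous block remains
        m2 = LVModel(model.dom, model.basis,
                     active=ActiveParams(k_av=0.0),
                     n_mu=3, n_nu=11, n_phi=12)
        co = m2.assemble(np.zeros(8), t=0.2)
        assert np.max(np.abs(co.alpha - co.alpha.T)) < 1e-10
        for _ in range(10):
            x = rng.normal(size=8)
            assert x @ co.alpha @ x >= -1e-12

    def test_grid_refinement_convergence(self, model):
        q = np.zeros(8)
        q[0] = 0.03
        coarse = model.assemble(q, t=-1.0)
        fine = LVModel(model.dom, model.basis, n_mu=5, n_nu=21,
                       n_phi=20).assemble(q, t=-1.0)
        finer = LVModel(model.dom, model.basis, n_mu=9, n_nu=41,
                        n_phi=40).assemble(q, t=-1.0)
        e1 = np.max(np.abs(coarse.kappa - finer.kappa))
        e2 = np.max(np.abs(fine.kappa - finer.kappa))
        assert e2 < e1 / 4.0   # order >= 2 in practice


class TestValves:
    circ = CirculationParams()

    def test_zero_driving_pressure(self):
        q_mv, q_aov, _, _ = valve_flows(self.circ.P_pv, self.circ.P_pv,
                                        self.circ)
        assert q_mv == pytest.approx(0.0, abs=1e-12)
        q_mv, q_aov, _, _ = valve_flows(80.0, 80.0, self.circ)
        assert q_aov == pytest.approx(0.0, abs=1e-12)

    def test_fully_open_linear_limit(self):
        P = self.circ.P_pv - 40.0
        q_mv, _, _, _ = valve_flows(P, 80.0, self.circ)
        assert q_mv == pytest.approx(40.0 / self.circ.R_mv, rel=1e-10)

    def test_monotone_in_pressure(self):
        # monotone throughout the conducting and near-closure range; in the
        # deep-closed tail the leakage only decays back to zero
        P = np.linspace(-20.0, self.circ.P_pv + 1.0, 200)
        q_mv = np.array([valve_flows(p, 80.0, self.circ)[0] for p in P])
        assert np.all(np.diff(q_mv) < 0)
        P = np.linspace(79.0, 200.0, 200)
        q_aov = np.array([valve_flows(p, 80.0, self.circ)[1] for p in P])
        assert np.all(np.diff(q_aov) > 0)

    def test_reverse_flow_negligible(self):
        q_mv, _, _, _ = valve_flows(self.circ.P_pv + 50.0, 80.0, self.circ)
        assert abs(q_mv) < 1e-12 * 50.0 / self.circ.R_mv


class TestRateSolve:
    def test_residuals_satisfied(self, model, rng):
        q = np.zeros(8)
        q[0] = 0.02
        co = model.assemble(q, t=0.55)   # mid-systole
        qdot, P = model.solve_rates(co, P_art=80.0)
        r1 = co.alpha @ qdot + co.kappa - co.eta * (P * KPA_PER_MMHG)
        assert np.max(np.abs(r1)) < 1e-8 * max(1.0, np.max(np.abs(co.kappa)))
        q_mv, q_aov, _, _ = valve_flows(P, 80.0, model.circ)
        r2 = co.eta @ qdot - q_mv + q_aov
        assert abs(r2) < 1e-8 * max(1.0, abs(q_mv) + abs(q_aov))

    def test_power_balance_identity(self, model):
        q = np.zeros(8)
        q[1] = 0.01
        co = model.assemble(q, t=0.5)
        qdot, P = model.solve_rates(co, P_art=75.0)
        lhs = qdot @ (co.alpha @ qdot + co.kappa)
        rhs = (P * KPA_PER_MMHG) * (co.eta @ qdot)
        assert lhs == pytest.approx(rhs, rel=1e-8, abs=1e-8)


class TestEquilibrium:
    def test_unloaded_state_is_reference(self, model):
        q = model.equilibrium_solve(0.0)
        assert np.max(np.abs(q)) < 1e-6

    def test_small_inflation_increases_volume(self, model):
        q = model.equilibrium_solve(2.0)
        v0 = float(model.cavity.cavity_volume(np.zeros(8)))
        v = float(model.cavity.cavity_volume(q))
        assert v > v0

    def test_inflation_curve_monotone(self, model):
        vols = []
        q = None
        for P in (0.0, 2.0, 4.0, 6.0):
            q = model.equilibrium_solve(P, q0=q)
            vols.append(float(model.cavity.cavity_volume(q)))
        assert np.all(np.diff(vols) > 0)


@pytest.fixture(scope="module")
def cycle_res(model):
    return model.simulate_cycle(n_cycles=3, steps_per_cycle=150, n_pre=1)


class TestCycle:
    def test_equilibrated_rest_is_fixed_point(self):
        from lvmodes.geometry import make_fixture_geometry
        m = LVModel(make_fixture_geometry("axisymmetric"), standard_basis(4),
                    active=ActiveParams(k_a=0.0, k_av=0.0),
                    circ=CirculationParams(P_pv=0.0, P_sv=0.0,
                                           P_art_init=0.0),
                    n_mu=3, n_nu=7, n_phi=8)
        res = m.simulate_cycle(n_cycles=1, steps_per_cycle=20, n_pre=0)
        assert np.max(np.abs(res.q)) < 1e-8
        assert np.max(np.abs(res.P_lv)) < 1e-8

    def test_physiological_ranges(self, cycle_res):
        assert 40.0 < cycle_res.stroke_volume() < 120.0
        assert 60.0 < cycle_res.P_lv.max() < 200.0
        assert cycle_res.stroke_work() > 0.2

    def test_volume_bookkeeping(self):
        # conservation of blood volume: the cavity-volume change over a
        # cycle equals the net valve inflow.  Needs the full 400 steps per
        # cycle to resolve the sharp valve-switching transients, so it runs
        # on a small dictionary.
        from lvmodes.geometry import make_fixture_geometry
        m = LVModel(make_fixture_geometry("axisymmetric"), standard_basis(4),
                    n_mu=3, n_nu=7, n_phi=8)
        res = m.simulate_cycle(n_cycles=1, steps_per_cycle=400, n_pre=1)
        s = res.cycle_slice(-1)
        dV = res.V_lv[s][-1] - res.V_lv[s][0]
        net = np.trapezoid(res.q_mv[s] - res.q_aov[s], res.time[s])
        assert abs(dV - net) < 0.005 * res.stroke_volume()

    def test_cycle_converges_to_periodic_state(self, cycle_res):
        w = [cycle_res.stroke_work(k) for k in range(3)]
        assert abs(w[2] - w[1]) / w[2] < 0.01

    def test_volume_consistent_with_cavity_model(self, model, cycle_res):
        k = len(cycle_res.time) // 2
        v = float(model.cavity.cavity_volume(cycle_res.q[k]))
        assert v == pytest.approx(cycle_res.V_lv[k], rel=1e-10)

    def test_temporal_convergence(self):
        from lvmodes.geometry import make_fixture_geometry
        m = LVModel(make_fixture_geometry("axisymmetric"), standard_basis(4),
                    n_mu=3, n_nu=7, n_phi=8)
        r1 = m.simulate_cycle(n_cycles=1, steps_per_cycle=150, n_pre=1)
        r2 = m.simulate_cycle(n_cycles=1, steps_per_cycle=300, n_pre=1)
        assert r1.stroke_work() == pytest.approx(r2.stroke_work(), rel=5e-3)
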