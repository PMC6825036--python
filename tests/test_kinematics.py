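import numpy as np
import pytest

from conftest import random_admissible_q
from lvmodes.kinematics import (AdmissibilityError, KinematicsEngine,
                                KinematicState, WallCollapseError,
                                deformation_gradient, solve_mu)
from lvmodes.modes import standard_basis


def torsion_only_q(basis, amount=0.15):
    q = np.zeros(basis.n_q)
    q[basis.block_slices["phi"].start] = amount   # uniform torsion term
    return q


class TestReferenceState:
    def test_identity_at_zero(self, engine_small):
        d = engine_small.evaluate(np.zeros(8))
        assert np.max(np.abs(d.F - np.eye(3))) < 1e-9
        assert np.max(np.abs(d.E)) < 1e-9
        assert np.max(np.abs(d.mu - engine_small.mu0)) < 1e-10
        assert np.max(np.abs(d.detF - 1)) < 1e-12

    def test_pure_torsion_keeps_mu_and_nu(self, engine_small, basis8):
        q = torsion_only_q(basis8)
        d = engine_small.evaluate(q)
        assert np.max(np.abs(d.mu - engine_small.mu0)) < 1e-12
        assert np.max(np.abs(d.nu - engine_small.nu0)) < 1e-12
        assert np.max(np.abs(d.detF - 1)) < 1e-12

    def test_apex_maps_to_itself(self, dom_asym, basis8, rng):
        eng = KinematicsEngine(dom_asym, basis8, [0.7], [np.pi], [1.0])
        q = rng.uniform(-0.1, 0.1, 8)
        d = eng.evaluate(q, check=False)
        assert float(np.real(d.nu[0])) == pytest.approx(np.pi, abs=1e-12)


class TestIncompressibility:
    def test_det_f_is_unity_for_admissible_states(self, engine_small, rng):
        for _ in range(5):
            q = random_admissible_q(engine_small, rng)
            d = engine_small.evaluate(q)
            assert np.max(np.abs(d.detF - 1)) < 1e-8

    def test_cubic_residual_at_solution(self, engine_small, rng):
        q = random_admissible_q(engine_small, rng)
        d = engine_small.evaluate(q)
        ch, cn = np.cosh(np.real(d.mu)), np.cos(np.real(d.nu))
        chin = np.cosh(np.real(d.muin))
        # residual of the integrated incompressibility relation
        w = lambda x, c: x ** 3 / 3 - c ** 2 * x
        R = (np.sin(d.nu) / np.sin(engine_small.nu0)) * (
            d.nu_nu0 * d.phi_phi0 - d.nu_phi0 * d.phi_nu0)
        lhs = w(ch, cn)
        rhs = w(chin, cn) + (engine_small.w_ref - engine_small.w_in0) / R
        assert np.max(np.abs(lhs - rhs)) < 1e-12

    def test_deformed_wall_volume_conserved(self, dom_asym):
        # independent route: divergence theorem over the deformed wall
        # boundary (endo + epi + base), no det F involved
        from lvmodes.constitutive import PassiveParams
        from lvmodes.verification import ManufacturedSolver
        from lvmodes.cavity import _cart_and_partials
        basis = standard_basis(8)
        solver = ManufacturedSolver(dom_asym, basis, n_mu=5, n_nu=31, n_phi=16)
        q = torsion_only_q(basis) + 0.0
        q[0] = 0.04  # inflate + twist
        total = 0.0
        for patch in solver.patches:
            eng = patch["engine"]
            d = eng.evaluate(q)
            x, x_mu, x_nu, x_phi = _cart_and_partials(
                d.mu, d.nu, d.phi, dom_asym.a)
            if patch["kind"] == "lateral":
                dmu_n = d.mu_mu0 * patch["dmu_dnu"] + d.mu_nu0
                dmu_p = d.mu_mu0 * patch["dmu_dphi"] + d.mu_phi0
                t1 = x_mu * dmu_n[:, None] + x_nu * d.nu_nu0[:, None] \
                    + x_phi * d.phi_nu0[:, None]
                t2 = x_mu * dmu_p[:, None] + x_nu * d.nu_phi0[:, None] \
                    + x_phi * d.phi_phi0[:, None]
                n_raw = patch["orient"] * np.cross(t1, t2)
            else:
                dn = np.tile(patch["dnuup_dphi"], patch["n_mu"])
                t1 = x_mu * d.mu_mu0[:, None]
                t2 = x_mu * (d.mu_phi0 + d.mu_nu0 * dn)[:, None] \
                    + x_nu * (d.nu_phi0 + d.nu_nu0 * dn)[:, None] \
                    + x_phi * (d.phi_phi0 + d.phi_nu0 * dn)[:, None]
                n_raw = np.cross(t1, t2)
            total += np.sum(np.einsum("na,na->n", np.real(x), np.real(n_raw))
                            * patch["w"]) / 3.0
        ref = float(np.sum(solver.grid.w_ref))
        assert total == pytest.approx(ref, rel=2e-3)

    def test_wall_collapse_detected(self, dom_asym, basis8):
        eng = KinematicsEngine(dom_asym, basis8, [0.62], [1.5], [0.3])
        q = np.zeros(8)
        q[0] = -0.6   # pull the endocardium through the axis
        with pytest.raises(WallCollapseError):
            eng.evaluate(q)

    def test_fold_over_detected(self, engine_small):
        q = np.zeros(8)
        q[engine_small.basis.block_slices["nu"].start] = -1.5
        with pytest.raises(AdmissibilityError):
            engine_small.evaluate(q)


class TestSensitivities:
    def test_strain_sensitivities_match_fd(self, engine_small, rng):
        q = random_admissible_q(engine_small, rng)
        dE = engine_small.strain_sensitivities(q)
        # step chosen above the cubic-solve evaluation-noise floor (~1e-10)
        # and below the truncation scale of the smooth kinematic map
        h = 1e-4
        for j in [0, 3, 6]:
            qp, qm = q.copy(), q.copy()
            qp[j] += h
            qm[j] -= h
            fd = (engine_small.evaluate(qp).E - engine_small.evaluate(qm).E) / (2 * h)
            scale = max(np.max(np.abs(fd)), 1e-10)
            assert np.max(np.abs(dE[j] - fd)) / scale < 1e-5

    def test_mu_partials_match_fd_of_solve(self, dom_asym, basis8, rng):
        q = KinematicState(q=rng.uniform(-0.04, 0.04, 8))
        mu0, nu0, phi0, h = 0.68, 2.1, 0.9, 1e-6
        d = deformation_gradient(mu0, nu0, phi0, q, basis8, dom_asym)
        fd = {
            "mu_mu0": (solve_mu(mu0 + h, nu0, phi0, q, basis8, dom_asym)
                       - solve_mu(mu0 - h, nu0, phi0, q, basis8, dom_asym)) / (2 * h),
            "mu_nu0": (solve_mu(mu0, nu0 + h, phi0, q, basis8, dom_asym)
                       - solve_mu(mu0, nu0 - h, phi0, q, basis8, dom_asym)) / (2 * h),
            "mu_phi0": (solve_mu(mu0, nu0, phi0 + h, q, basis8, dom_asym)
                        - solve_mu(mu0, nu0, phi0 - h, q, basis8, dom_asym)) / (2 * h),
        }
        for key, want in fd.items():
            got = float(np.real(getattr(d, key)[0]))
            assert got == pytest.approx(want, rel=1e-5, abs=1e-9)


class TestStructure:
    def test_lower_left_block_of_f_is_zero(self, engine_small, rng):
        q = random_admissible_q(engine_small, rng)
        d = engine_small.evaluate(q)
        assert np.all(d.F[:, 1, 0] == 0.0)
        assert np.all(d.F[:, 2, 0] == 0.0)

    def test_strain_tensors_symmetric(self, engine_small, rng):
        q = random_admissible_q(engine_small, rng)
        d = engine_small.evaluate(q)
        assert np.max(np.abs(d.E - np.swapaxes(d.E, -1, -2))) < 1e-12
        e = d.e
        assert np.max(np.abs(e - np.swapaxes(e, -1, -2))) < 1e-12

    def test_fiber_stretch_positive(self, engine_small, rng):
        from lvmodes.constitutive import to_fiber_frame
        from lvmodes.fibers import fiber_basis
        q = random_admissible_q(engine_small, rng)
        d = engine_small.evaluate(q)
        Q = fiber_basis(engine_small.mu0, engine_small.nu0,
                        engine_small.phi0, engine_small.dom)
        Eff = to_fiber_frame(d.E.real, Q)[:, 2, 2]
        lam = np.sqrt(2 * Eff + 1)
        assert np.all(np.isfinite(lam)) and np.all(lam > 0)

    def test_state_validation(self):
        with pytest.raises(ValueError):
            KinematicState(q=np.array([np.nan, 0.0]))
        with pytest.raises(ValueError):
            KinematicState(q=np.zeros(3), qdot=np.zeros(4))
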