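"""Virtual-work ODE system and cardiac-cycle integration.

Contracting the weak equilibrium statement with each mode variation gives
one equation per kinematic variable:

    sum_j alpha_ij dq_j/dt + kappa_i - eta_i P_lv = 0,        i = 1..N_q

with
    alpha_ij = int dE/dq_i : (S_vq_j + S_aq_j) dV0      (kPa cm^3 s)
    kappa_i  = int dE/dq_i : (S_e + S_a0)     dV0      (kPa cm^3)
    eta_i    = dV_lv/dq_i                               (cm^3)

closed by conservation of blood volume, eta . dq/dt = q_mv - q_aov.  The
mitral and aortic valves are smooth pressure-gated resistances and the
arterial afterload is a two-element windkessel returning to a constant
venous pressure; pulmonary venous pressure is constant.  Eliminating
dq/dt = alpha^-1 (eta P - kappa) leaves a scalar equation in P_lv, solved
by safeguarded Newton at every integration stage.  Time stepping is
classical RK4 with per-stage coefficient evaluation.

Internal pressure unit is kPa (consistent with kPa stresses and cm^3
volumes); the circulation interface and all outputs use mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cavity import CavityModel
from .constitutive import (ActiveParams, PassiveParams, active_pk2,
                           passive_pk2, to_fiber_frame, viscous_pk2)
from .fibers import FiberArchitecture, fiber_basis
from .geometry import QuadratureGrid, ReferenceDomain, wall_volume
from .kinematics import KinematicsEngine
from .modes import ModeBasisSpec

__all__ = [
    "KPA_PER_MMHG",
    "VirtualWorkCoefficients",
    "CirculationParams",
    "CardiacCycleResult",
    "valve_flows",
    "LVModel",
]

KPA_PER_MMHG = 0.1333223684


class SolverError(RuntimeError):
    """Newton iteration failed to converge; carries the final residual."""


@dataclass
class VirtualWorkCoefficients:
    alpha: np.ndarray   # (N_q, N_q), kPa cm^3 s
    kappa: np.ndarray   # (N_q,), kPa cm^3
    eta: np.ndarray     # (N_q,), cm^3


@dataclass(frozen=True)
class CirculationParams:
    """Lumped preload/afterload circuit (mmHg, mL, s).

    Venous pressures are constant; valves are smooth monotone diode laws
    q = (dP/R) sigma(dP / p_steep); the afterload is a two-element
    windkessel (R_per, C_art) draining to the systemic venous pressure.
    """

    P_pv: float = 10.0
    P_sv: float = 4.0
    R_mv: float = 0.01
    R_aov: float = 0.006
    p_steep: float = 1.0
    R_per: float = 1.05
    C_art: float = 1.8
    P_art_init: float = 85.0

    def __post_init__(self):
        if min(self.R_mv, self.R_aov, self.R_per, self.C_art,
               self.p_steep) <= 0:
            raise ValueError("resistances, compliance and valve steepness "
                             "must be positive")


def _gated(dp, R, ps):
    """Smooth diode flow and its derivative with respect to dp.

    q = (dp/R) sigma(dp/ps): linear conduction for forward pressure,
    exponentially small reverse leakage.  Strictly monotone on the
    conducting side (dp > -ps); in the deep reverse tail the leakage decays
    back toward zero, which is physically irrelevant at ~1e-3 mL/s."""
    x = np.clip(dp / ps, -500.0, 500.0)
    sig = 1.0 / (1.0 + np.exp(-x))
    q = dp / R * sig
    dq = sig / R + dp / R * sig * (1.0 - sig) / ps
    return q, dq


def valve_flows(P_lv, P_art, circ: CirculationParams):
    """Mitral and aortic flows (mL/s) and their dP_lv-derivatives (mmHg)."""
    q_mv, d_mv = _gated(circ.P_pv - P_lv, circ.R_mv, circ.p_steep)
    q_aov, d_aov = _gated(P_lv - P_art, circ.R_aov, circ.p_steep)
    return q_mv, q_aov, -d_mv, d_aov


@dataclass
class CardiacCycleResult:
    """Time series of one simulation run (outputs in mmHg, mL, mL/s)."""

    time: np.ndarray
    q: np.ndarray
    P_lv: np.ndarray
    V_lv: np.ndarray
    q_mv: np.ndarray
    q_aov: np.ndarray
    P_art: np.ndarray
    period: float
    mode_ordering: list = field(default_factory=list)

    def cycle_slice(self, k=-1):
        """Index slice of the k-th full cycle (default: last)."""
        n_cyc = int(round(self.time[-1] / self.period))
        steps = (len(self.time) - 1) // n_cyc
        k = k % n_cyc
        return slice(k * steps, (k + 1) * steps + 1)

    def stroke_work(self, k=-1):
        """Loop integral oint P_lv dV_lv over cycle k (J/cycle), trapezoidal.

        Positive for the counter-clockwise physiological loop (ejection at
        high pressure, filling at low pressure).
        """
        s = self.cycle_slice(k)
        P = self.P_lv[s] * KPA_PER_MMHG
        V = self.V_lv[s]
        return float(-(P[:-1] + P[1:]) @ np.diff(V) / 2.0 / 1000.0)

    def stroke_volume(self, k=-1):
        s = self.cycle_slice(k)
        return float(self.V_lv[s].max() - self.V_lv[s].min())


class LVModel:
    """Assembled left-ventricle model: geometry + modes + material +
    circulation, with equilibrium and cardiac-cycle solvers."""

    def __init__(self, dom: ReferenceDomain, basis: ModeBasisSpec,
                 passive: PassiveParams = PassiveParams(),
                 active: ActiveParams = ActiveParams(),
                 circ: CirculationParams = CirculationParams(),
                 arch: FiberArchitecture = FiberArchitecture(),
                 n_mu=5, n_nu=21, n_phi=20):
        self.dom = dom
        self.basis = basis
        self.passive = passive
        self.active = active
        self.circ = circ
        self.grid = QuadratureGrid.build(dom, n_mu=n_mu, n_nu=n_nu, n_phi=n_phi)
        self.engine = KinematicsEngine(dom, basis,
                                       self.grid.mu0, self.grid.nu0,
                                       self.grid.phi0)
        self.Q_fiber = fiber_basis(self.grid.mu0, self.grid.nu0,
                                   self.grid.phi0, dom, arch)
        self.cavity = CavityModel(dom, basis, n_nu=n_nu, n_phi=n_phi)
        self.wall_volume = wall_volume(dom, self.grid)

    # -- coefficient assembly ----------------------------------------------

    def assemble(self, q, t) -> VirtualWorkCoefficients:
        """Virtual-work coefficients at state q and cycle time t."""
        w = self.grid.w_ref
        Q = self.Q_fiber
        d = self.engine.evaluate(q)
        dE = self.engine.strain_sensitivities(q)

        E_fib = to_fiber_frame(d.E.real, Q)
        lam = np.sqrt(np.clip(2.0 * E_fib[:, 2, 2] + 1.0, 1e-12, None))
        dE_fib_ff = np.einsum("na,jnab,nb->jn", Q[:, :, 2], dE, Q[:, :, 2])
        dlam = dE_fib_ff / lam[None, :]

        S_e = passive_pk2(E_fib, self.passive, Q)
        S_a0, S_aq = active_pk2(t, lam, dlam, self.active, Q)
        S_vq, _ = viscous_pk2(d.C.real, dE, None, self.passive.k_v)

        alpha = np.einsum("inab,jnab,n->ij", dE, S_vq + S_aq, w)
        kappa = np.einsum("inab,nab,n->i", dE, S_e + S_a0, w)
        eta = self.cavity.volume_gradient(q)
        return VirtualWorkCoefficients(alpha=alpha, kappa=kappa, eta=eta)

    # -- rate solve ---------------------------------------------------------

    def solve_rates(self, coeffs: VirtualWorkCoefficients, P_art,
                    P_guess=None, tol=1e-10, max_iter=60):
        """Rates dq/dt and the LV pressure closing the volume constraint.

        Eliminates dq/dt = alpha^-1 (eta P - kappa); the remaining scalar
        residual  eta . dq/dt - q_mv(P) + q_aov(P)  is strictly monotone in
        P and solved by Newton with a bisection safeguard.  P in mmHg.
        """
        al, ka, eta = coeffs.alpha, coeffs.kappa, coeffs.eta
        try:
            sol = np.linalg.solve(al, np.stack([eta, ka], axis=-1))
        except np.linalg.LinAlgError as err:
            raise SolverError("singular alpha matrix") from err
        ai_eta, ai_ka = sol[:, 0], sol[:, 1]
        s1 = float(eta @ ai_eta) * KPA_PER_MMHG   # mL/s per mmHg
        s0 = -float(eta @ ai_ka)                  # mL/s

        def resid(P):
            q_mv, q_aov, d_mv, d_aov = valve_flows(P, P_art, self.circ)
            return s0 + s1 * P - q_mv + q_aov, s1 - d_mv + d_aov

        P = float(P_guess) if P_guess is not None else self.circ.P_pv
        lo, hi = -100.0, 500.0
        scale = max(1.0, abs(s0))
        for _ in range(max_iter):
            r, dr = resid(P)
            if abs(r) < tol * scale:
                break
            if r > 0:
                hi = min(hi, P)
            else:
                lo = max(lo, P)
            P_new = P - r / dr
            if not lo < P_new < hi:
                P_new = 0.5 * (lo + hi)
            P = P_new
        else:
            raise SolverError(f"pressure Newton stalled, residual {r:.3e}")
        qdot = ai_eta * (P * KPA_PER_MMHG) - ai_ka
        return qdot, P

    # -- time integration ----------------------------------------------------

    def simulate_cycle(self, n_cycles=3, steps_per_cycle=400, period=0.8,
                       q0=None, n_pre=1) -> CardiacCycleResult:
        """Integrate full cardiac cycles with classical RK4.

        Starts from the unstressed state (q = 0 by default); ``n_pre``
        unrecorded preparatory cycles let venous filling establish a
        physiological end-diastolic state before the reported cycles.
        """
        nq = self.basis.n_q
        q = np.zeros(nq) if q0 is None else np.asarray(q0, float).copy()
        P_art = self.circ.P_art_init
        dt = period / steps_per_cycle
        n_tot = (n_pre + n_cycles) * steps_per_cycle
        rec_from = n_pre * steps_per_cycle

        P_guess = [self.circ.P_pv]

        def rhs(t_abs, y):
            qq, pa = y[:nq], y[nq]
            co = self.assemble(qq, t_abs % period)
            qdot, P = self.solve_rates(co, pa, P_guess=P_guess[0])
            P_guess[0] = P
            _, q_aov, _, _ = valve_flows(P, pa, self.circ)
            pa_dot = (q_aov - (pa - self.circ.P_sv) / self.circ.R_per) \
                / self.circ.C_art
            return np.concatenate([qdot, [pa_dot]]), P

        rows = []

        def record(t_abs, y):
            qq, pa = y[:nq], y[nq]
            co = self.assemble(qq, t_abs % period)
            qdot, P = self.solve_rates(co, pa, P_guess=P_guess[0])
            q_mv, q_aov, _, _ = valve_flows(P, pa, self.circ)
            V = float(np.real(self.cavity.cavity_volume(qq)))
            rows.append((t_abs - n_pre * period, qq.copy(), P, V,
                         float(q_mv), float(q_aov), pa))

        y = np.concatenate([q, [P_art]])
        for m in range(n_tot):
            t = m * dt
            if m == rec_from:
                record(t, y)
            k1, _ = rhs(t, y)
            k2, _ = rhs(t + dt / 2, y + dt / 2 * k1)
            k3, _ = rhs(t + dt / 2, y + dt / 2 * k2)
            k4, _ = rhs(t + dt, y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            if m >= rec_from:
                record((m + 1) * dt, y)

        t_arr = np.array([r[0] for r in rows])
        return CardiacCycleResult(
            time=t_arr,
            q=np.array([r[1] for r in rows]),
            P_lv=np.array([r[2] for r in rows]),
            V_lv=np.array([r[3] for r in rows]),
            q_mv=np.array([r[4] for r in rows]),
            q_aov=np.array([r[5] for r in rows]),
            P_art=np.array([r[6] for r in rows]),
            period=period,
            mode_ordering=self.basis.ordering(),
        )

    # -- equilibrium ---------------------------------------------------------

    def equilibrium_residual(self, q, P_lv_mmhg, t=None):
        """kappa(q) - eta(q) P_lv  (kPa cm^3); activation included if a
        cycle time is given."""
        co = self.assemble(q, t if t is not None else -1.0)
        return co.kappa - co.eta * (P_lv_mmhg * KPA_PER_MMHG)

    def equilibrium_solve(self, P_lv_mmhg, t=None, q0=None, tol=None,
                          max_iter=30):
        """Static state q with kappa = eta P_lv (the virtual-work system
        with rates dropped), by damped Newton with finite-difference
        Jacobian."""
        nq = self.basis.n_q
        q = np.zeros(nq) if q0 is None else np.asarray(q0, float).copy()
        scale = self.passive.k_e * self.wall_volume
        tol = 1e-9 * scale if tol is None else tol

        r = self.equilibrium_residual(q, P_lv_mmhg, t)
        for _ in range(max_iter):
            if np.max(np.abs(r)) < tol:
                return q
            J = self._fd_jacobian(
                lambda x: self.equilibrium_residual(x, P_lv_mmhg, t), q, r)
            dq = np.linalg.solve(J, -r)
            lam = 1.0
            for _ in range(12):
                try:
                    r_new = self.equilibrium_residual(q + lam * dq,
                                                      P_lv_mmhg, t)
                except Exception:
                    lam *= 0.5
                    continue
                if np.linalg.norm(r_new) < np.linalg.norm(r):
                    break
                lam *= 0.5
            else:
                raise SolverError(
                    f"equilibrium line search failed, |r|={np.max(np.abs(r)):.3e}")
            q = q + lam * dq
            r = r_new
        if np.max(np.abs(r)) < tol:
            return q
        raise SolverError(
            f"equilibrium Newton did not converge, |r|={np.max(np.abs(r)):.3e}")

    @staticmethod
    def _fd_jacobian(fun, q, r0, h=1e-6):
        nq = q.size
        J = np.empty((r0.size, nq))
        for j in range(nq):
            qp = q.copy()
            qp[j] += h
            J[:, j] = (fun(qp) - r0) / h
        return J
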