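"""Incompressible kinematics of the deformation-mode model.

The three displacement functions move the endocardial surface radially
(``mu_in``) and remap the angular coordinates (``nu``, ``phi``); the radial
coordinate ``mu`` of every interior material point then follows from exact
volume conservation.  Writing ``W(mu, nu) = cosh^3(mu)/3 - cosh(mu) cos^2(nu)``
(the antiderivative of the prolate volume element in ``cosh mu``), the
incompressibility condition det F = 1 integrates to the cubic relation

    W(mu, nu) = W(mu_in, nu) + [W(mu0, nu0) - W(mu_in0, nu0)] / R,

where ``R = (sin nu / sin nu0) (nu_,nu0 phi_,phi0 - nu_,phi0 phi_,nu0)`` is
the angular area ratio of the mapping.  The constant of integration is fixed
so the endocardial surface maps onto itself (``mu0 = mu_in0  ->  mu = mu_in``
exactly).  The cubic in ``cosh mu`` is strictly monotone for ``cosh mu >= 1
>= |cos nu|``, so the admissible root is unique; it is found by a guarded
Newton iteration polished to round-off.

All evaluation is vectorized over point sets and dtype-generic: evaluating
at a complex kinematic vector propagates derivatives exactly through the
implicit ``mu`` solve, which is how the strain sensitivities dE/dq are
obtained (complex-step differentiation, no subtractive cancellation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ReferenceDomain, prolate_to_cartesian, scale_factors
from .modes import ModeBasisSpec, basis_matrix

__all__ = [
    "AdmissibilityError",
    "WallCollapseError",
    "KinematicState",
    "PointDeformation",
    "KinematicsEngine",
    "solve_mu",
    "deformation_gradient",
]

#: complex-step size; exact to round-off, no cancellation
CS_STEP = 1e-30


class AdmissibilityError(ValueError):
    """The kinematic state folds the angular mapping over itself."""


class WallCollapseError(AdmissibilityError):
    """The deformation leaves no admissible root for the wall coordinate."""


@dataclass
class KinematicState:
    """Kinematic variables ``q`` (dimensionless) and optional rates (1/s)."""

    q: np.ndarray
    qdot: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        if not np.all(np.isfinite(self.q)):
            raise ValueError("q must be finite")
        if self.qdot is not None:
            self.qdot = np.asarray(self.qdot, float)
            if self.qdot.shape != self.q.shape:
                raise ValueError("qdot length must match q")


def _w(ch, cn):
    """Volume potential W as a function of cosh(mu) and cos(nu)."""
    return ch**3 / 3.0 - ch * cn**2


def _w_mu(ch, sh, cn):
    """dW/dmu = sinh(mu) (cosh^2 mu - cos^2 nu)."""
    return sh * (ch**2 - cn**2)


def _w_nu(ch, sn, cn):
    """dW/dnu = cosh(mu) sin(2 nu)."""
    return ch * 2.0 * sn * cn


def _solve_cubic(wt, cn, ch_lo):
    """Root cosh(mu) >= ch_lo >= 1 of  x^3/3 - cn^2 x = wt  (vectorized).

    Monotone increasing and convex for x >= 1 >= |cn|; Newton converges
    from any start > |cn|.  Complex inputs ride along exactly.
    """
    real = not np.iscomplexobj(wt)
    lo = np.real(ch_lo)
    if real and np.any(wt < _w(np.ones_like(cn), cn) - 1e-9):
        raise WallCollapseError("deformation collapses the wall: no admissible root")
    x = np.maximum(lo, np.cbrt(3.0 * np.maximum(np.real(wt), 0.0) + 1.0))
    x = x.astype(wt.dtype) if not real else x
    for _ in range(100):
        f = x**3 / 3.0 - cn**2 * x - wt
        step = f / (x * x - cn**2)
        x = x - step
        if np.max(np.abs(step)) < 1e-15:
            break
    if real:
        x = np.maximum(x, 1.0)
    return x


@dataclass
class PointDeformation:
    """Deformation state at material points (arrays over the point set)."""

    mu: np.ndarray
    nu: np.ndarray
    phi: np.ndarray
    F: np.ndarray          # (n, 3, 3) prolate physical components
    C: np.ndarray          # (n, 3, 3)
    E: np.ndarray          # (n, 3, 3) Green strain
    detF: np.ndarray
    # coordinate-map partials, kept for surface tangent assembly
    mu_mu0: np.ndarray
    mu_nu0: np.ndarray
    mu_phi0: np.ndarray
    nu_nu0: np.ndarray
    nu_phi0: np.ndarray
    phi_nu0: np.ndarray
    phi_phi0: np.ndarray
    muin: np.ndarray
    muin_nu0: np.ndarray
    muin_phi0: np.ndarray

    @property
    def B(self):
        return self.F @ np.swapaxes(self.F, -1, -2)

    @property
    def e(self):
        """Euler-Almansi strain (I - B^-1)/2."""
        eye = np.eye(3, dtype=self.F.dtype)
        return 0.5 * (eye - np.linalg.inv(self.B))


class KinematicsEngine:
    """Deformation evaluator bound to a domain, mode dictionary and points.

    Precomputes everything that does not depend on the kinematic state
    (spline surface values and partials, mode basis matrices, reference
    scale factors), so repeated evaluation over states — including the
    N_q complex-step sweeps behind dE/dq — costs only dense linear algebra
    and the vectorized cubic solve.
    """

    def __init__(self, dom: ReferenceDomain, basis: ModeBasisSpec,
                 mu0, nu0, phi0):
        self.dom = dom
        self.basis = basis
        self.mu0 = np.atleast_1d(np.asarray(mu0, float))
        self.nu0 = np.atleast_1d(np.asarray(nu0, float))
        self.phi0 = np.atleast_1d(np.asarray(phi0, float))
        n = self.mu0.size
        if self.nu0.size != n or self.phi0.size != n:
            raise ValueError("point coordinate arrays must have equal length")

        a = dom.a
        self.m_in0 = np.asarray(dom.mu_in0(self.nu0, self.phi0))
        self.m_in0_nu = np.asarray(dom.mu_in0(self.nu0, self.phi0, dnu=1))
        self.m_in0_phi = np.asarray(dom.mu_in0(self.nu0, self.phi0, dphi=1))

        self.ch0, self.sh0 = np.cosh(self.mu0), np.sinh(self.mu0)
        self.cn0, self.sn0 = np.cos(self.nu0), np.sin(self.nu0)
        chi, shi = np.cosh(self.m_in0), np.sinh(self.m_in0)
        self.w_ref = _w(self.ch0, self.cn0)
        self.w_mu_ref = _w_mu(self.ch0, self.sh0, self.cn0)
        self.w_in0 = _w(chi, self.cn0)
        self.w_mu_in0 = _w_mu(chi, shi, self.cn0)
        self.w_nu_ref = _w_nu(self.ch0, self.sn0, self.cn0)
        self.w_nu_in0 = _w_nu(chi, self.sn0, self.cn0)
        self.g_mu0, self.g_nu0, self.g_phi0 = scale_factors(self.mu0, self.nu0, a)

        # mode basis matrices: value + partials up to second order
        orders = [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)]
        self._B = {}
        for block in ("mu", "nu", "phi"):
            terms = basis.terms(block)
            self._B[block] = {
                o: basis_matrix(terms, self.nu0, self.phi0, dnu=o[0], dphi=o[1])
                for o in orders
            }
        self._slices = basis.block_slices

    # -- displacement-field evaluation -------------------------------------

    def _fields(self, q, block):
        qb = np.asarray(q)[self._slices[block]]
        B = self._B[block]
        return {o: B[o] @ qb for o in B}

    def evaluate(self, q, check=True) -> PointDeformation:
        """Full point deformation at kinematic vector ``q``.

        ``q`` may be complex for derivative propagation; admissibility is
        checked on the real part only when ``check`` is set.
        """
        q = np.asarray(q)
        if q.shape != (self.basis.n_q,):
            raise ValueError(
                f"q must have length {self.basis.n_q}, got {q.shape}")
        fm = self._fields(q, "mu")
        fn = self._fields(q, "nu")
        fp = self._fields(q, "phi")

        nu = self.nu0 + fn[(0, 0)]
        phi = self.phi0 + fp[(0, 0)]
        muin = self.m_in0 + fm[(0, 0)]
        muin_nu0 = self.m_in0_nu + fm[(1, 0)]
        muin_phi0 = self.m_in0_phi + fm[(0, 1)]

        nu_n, nu_p = 1.0 + fn[(1, 0)], fn[(0, 1)]
        phi_n, phi_p = fp[(1, 0)], 1.0 + fp[(0, 1)]
        D = nu_n * phi_p - nu_p * phi_n
        sn, cn = np.sin(nu), np.cos(nu)
        s = sn / self.sn0
        R = s * D

        if check and not np.iscomplexobj(q):
            if np.any(np.real(nu) <= 0.0) or np.any(np.real(nu) > np.pi + 1e-12):
                raise AdmissibilityError("nu displaced outside (0, pi]: fold-over")
            if np.any(np.real(nu_n) <= 0.0) or np.any(np.real(R) <= 0.0):
                raise AdmissibilityError("angular mapping folds over (R <= 0)")
            if not (np.all(np.isfinite(muin)) and np.all(np.real(muin) < 10.0)):
                raise AdmissibilityError("endocardial surface displaced out of range")
            if np.any(np.real(muin) <= 0.0):
                raise WallCollapseError(
                    "endocardial surface collapses through the axis")

        chin, shin = np.cosh(muin), np.sinh(muin)
        w_in = _w(chin, cn)
        dG0 = self.w_ref - self.w_in0
        wt = w_in + dG0 / R
        ch = _solve_cubic(wt, cn, chin)
        sh = np.sqrt(ch * ch - 1.0)
        mu = np.arccosh(ch) if not np.iscomplexobj(ch) else np.arccosh(ch + 0j)

        w_mu = _w_mu(ch, sh, cn)
        w_nu = _w_nu(ch, sn, cn)
        w_mu_in = _w_mu(chin, shin, cn)
        w_nu_in = _w_nu(chin, sn, cn)

        # derivatives of R in the reference angles (second-order mode terms)
        s_n = cn * nu_n / self.sn0 - sn * self.cn0 / self.sn0**2
        s_p = cn * nu_p / self.sn0
        D_n = fn[(2, 0)] * phi_p + nu_n * fp[(1, 1)] - fn[(1, 1)] * phi_n \
            - nu_p * fp[(2, 0)]
        D_p = fn[(1, 1)] * phi_p + nu_n * fp[(0, 2)] - fn[(0, 2)] * phi_n \
            - nu_p * fp[(1, 1)]
        R_n = s_n * D + s * D_n
        R_p = s_p * D + s * D_p

        dG0_n = self.w_nu_ref - (self.w_mu_in0 * self.m_in0_nu + self.w_nu_in0)
        dG0_p = -self.w_mu_in0 * self.m_in0_phi

        wt_n = w_mu_in * muin_nu0 + w_nu_in * nu_n \
            + (dG0_n * R - dG0 * R_n) / R**2
        wt_p = w_mu_in * muin_phi0 + w_nu_in * nu_p \
            + (dG0_p * R - dG0 * R_p) / R**2

        mu_m0 = self.w_mu_ref / (R * w_mu)
        mu_n0 = (wt_n - w_nu * nu_n) / w_mu
        mu_p0 = (wt_p - w_nu * nu_p) / w_mu

        a = self.dom.a
        g = a * np.sqrt(sh * sh + sn * sn)
        g_phi = a * sh * sn

        n = self.mu0.size
        F = np.zeros((n, 3, 3), dtype=ch.dtype)
        F[:, 0, 0] = g / self.g_mu0 * mu_m0
        F[:, 0, 1] = g / self.g_nu0 * mu_n0
        F[:, 0, 2] = g / self.g_phi0 * mu_p0
        F[:, 1, 1] = g / self.g_nu0 * nu_n
        F[:, 1, 2] = g / self.g_phi0 * nu_p
        F[:, 2, 1] = g_phi / self.g_nu0 * phi_n
        F[:, 2, 2] = g_phi / self.g_phi0 * phi_p

        C = np.swapaxes(F, -1, -2) @ F
        E = 0.5 * (C - np.eye(3, dtype=F.dtype))
        detF = F[:, 0, 0] * (F[:, 1, 1] * F[:, 2, 2] - F[:, 1, 2] * F[:, 2, 1])

        return PointDeformation(
            mu=mu, nu=nu, phi=phi, F=F, C=C, E=E, detF=detF,
            mu_mu0=mu_m0, mu_nu0=mu_n0, mu_phi0=mu_p0,
            nu_nu0=nu_n, nu_phi0=nu_p, phi_nu0=phi_n, phi_phi0=phi_p,
            muin=muin, muin_nu0=muin_nu0, muin_phi0=muin_phi0,
        )

    def positions(self, q):
        """Deformed Cartesian positions x(X; q) at the point set."""
        d = self.evaluate(q, check=False)
        x, y, z = prolate_to_cartesian(d.mu, d.nu, d.phi, self.dom.a)
        return np.stack([x, y, z], axis=-1)

    def reference_positions(self):
        x, y, z = prolate_to_cartesian(self.mu0, self.nu0, self.phi0, self.dom.a)
        return np.stack([x, y, z], axis=-1)

    # -- sensitivities ------------------------------------------------------

    def strain_sensitivities(self, q, want_positions=False):
        """dE/dq (and optionally dx/dq) by complex-step differentiation.

        Returns ``dE`` with shape (N_q, n, 3, 3) and, if requested, ``dx``
        with shape (N_q, n, 3).
        """
        q = np.asarray(q, float)
        nq = self.basis.n_q
        n = self.mu0.size
        dE = np.empty((nq, n, 3, 3))
        dx = np.empty((nq, n, 3)) if want_positions else None
        for j in range(nq):
            qc = q.astype(complex)
            qc[j] += 1j * CS_STEP
            d = self.evaluate(qc, check=False)
            dE[j] = d.E.imag / CS_STEP
            if want_positions:
                x, y, z = prolate_to_cartesian(d.mu, d.nu, d.phi, self.dom.a)
                dx[j] = np.stack([x.imag, y.imag, z.imag], axis=-1) / CS_STEP
        return (dE, dx) if want_positions else dE


# -- scalar convenience wrappers -------------------------------------------

def solve_mu(mu0, nu0, phi0, state, basis, dom):
    """Deformed ``mu`` at a single reference point (incompressibility solve)."""
    eng = KinematicsEngine(dom, basis, [mu0], [nu0], [phi0])
    return float(np.real(eng.evaluate(np.asarray(state.q)).mu[0]))


def deformation_gradient(mu0, nu0, phi0, state, basis, dom) -> PointDeformation:
    """Full deformation state at a single reference point."""
    eng = KinematicsEngine(dom, basis, [mu0], [nu0], [phi0])
    return eng.evaluate(np.asarray(state.q))
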