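"""LV cavity: endocardial surface, closing cap, chamber volume and its
mode sensitivities.

The chamber is bounded by the deformed endocardial surface and, at the
base, by a closing cap so that a volume (and the pressure work P dV) is
well defined.  The cap is a ruled surface: straight segments from the
deformed basal endocardial rim to the rim centroid projected onto the long
axis.  The cavity volume is computed by the divergence theorem,
V = (1/3) oint x . n dS over the closed surface, with outward normals.

Because the whole construction is a smooth function of the kinematic
vector q, the pressure virtual-work vector eta used by the dynamics is
obtained as the exact gradient of the discrete volume (complex step),
which enforces the energy identity eta = grad_q V_lv by construction.  The
direct surface-integral form of eta (endocardial term plus cap term) is
also provided as an independent consistency route.
"""

from __future__ import annotations

import numpy as np

from .geometry import APEX_OFFSET, ReferenceDomain, periodic_simpson_weights
from .modes import ModeBasisSpec, basis_matrix

__all__ = ["CavityModel"]

_CS = 1e-30


def _cart_and_partials(mu, nu, phi, a):
    """Deformed Cartesian position and its partials in (mu, nu, phi)."""
    sh, ch = np.sinh(mu), np.cosh(mu)
    sn, cn = np.sin(nu), np.cos(nu)
    cp, sp = np.cos(phi), np.sin(phi)
    x = np.stack([a * sh * sn * cp, a * sh * sn * sp, a * ch * cn], axis=-1)
    x_mu = np.stack([a * ch * sn * cp, a * ch * sn * sp, a * sh * cn], axis=-1)
    x_nu = np.stack([a * sh * cn * cp, a * sh * cn * sp, -a * ch * sn], axis=-1)
    x_phi = np.stack([-a * sh * sn * sp, a * sh * sn * cp,
                      np.zeros_like(sh)], axis=-1)
    return x, x_mu, x_nu, x_phi


def _simpson(n):
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w / 3.0 / (n - 1)


class CavityModel:
    """Chamber-volume machinery bound to a domain and mode dictionary."""

    def __init__(self, dom: ReferenceDomain, basis: ModeBasisSpec,
                 n_nu=21, n_phi=20, n_ur=3):
        self.dom = dom
        self.basis = basis
        a = dom.a

        phi = np.arange(n_phi) * 2.0 * np.pi / n_phi
        w_phi = periodic_simpson_weights(n_phi)
        nu_lo = np.asarray(dom.nu_up0(phi))
        nu_hi = np.pi - APEX_OFFSET
        s = np.linspace(0.0, 1.0, n_nu)
        nu = nu_lo[None, :] + s[:, None] * (nu_hi - nu_lo[None, :])
        w_nu = (_simpson(n_nu)[:, None] * (nu_hi - nu_lo)[None, :])
        self._endo_w = (w_nu * w_phi[None, :]).ravel()
        self._endo_nu = nu.ravel()
        self._endo_phi = np.broadcast_to(phi, nu.shape).ravel().copy()

        # basal rim curve nodes
        self._rim_phi = phi
        self._rim_nu = nu_lo
        self._rim_dnu = np.asarray(dom.nu_up0(phi, dphi=1))
        self._rim_wphi = w_phi

        # cap radial rule (integrand is quadratic in u_r: Simpson is exact)
        self._ur = np.linspace(0.0, 1.0, n_ur)
        self._w_ur = _simpson(n_ur)

        self._pre = {}
        for tag, nn, pp in (("endo", self._endo_nu, self._endo_phi),
                            ("rim", self._rim_nu, self._rim_phi)):
            d = {
                "m0": np.asarray(dom.mu_in0(nn, pp)),
                "m0_nu": np.asarray(dom.mu_in0(nn, pp, dnu=1)),
                "m0_phi": np.asarray(dom.mu_in0(nn, pp, dphi=1)),
                "nu0": nn, "phi0": pp,
            }
            for block in ("mu", "nu", "phi"):
                terms = basis.terms(block)
                d[block] = {
                    o: basis_matrix(terms, nn, pp, dnu=o[0], dphi=o[1])
                    for o in [(0, 0), (1, 0), (0, 1)]
                }
            self._pre[tag] = d
        self._sl = basis.block_slices

    # -- deformed surface fields -------------------------------------------

    def _surface(self, q, tag):
        """Deformed (mu_in, nu, phi) and their (nu0, phi0) partials."""
        p = self._pre[tag]
        q = np.asarray(q)
        out = {}
        for block in ("mu", "nu", "phi"):
            qb = q[self._sl[block]]
            out[block] = {o: p[block][o] @ qb for o in p[block]}
        muin = p["m0"] + out["mu"][(0, 0)]
        muin_n = p["m0_nu"] + out["mu"][(1, 0)]
        muin_p = p["m0_phi"] + out["mu"][(0, 1)]
        nu = p["nu0"] + out["nu"][(0, 0)]
        nu_n = 1.0 + out["nu"][(1, 0)]
        nu_p = out["nu"][(0, 1)]
        phi = p["phi0"] + out["phi"][(0, 0)]
        phi_n = out["phi"][(1, 0)]
        phi_p = 1.0 + out["phi"][(0, 1)]
        return muin, muin_n, muin_p, nu, nu_n, nu_p, phi, phi_n, phi_p

    def endo_points_and_tangents(self, q):
        """Deformed endocardial positions and parametric tangents t_nu0, t_phi0."""
        muin, muin_n, muin_p, nu, nu_n, nu_p, phi, phi_n, phi_p = \
            self._surface(q, "endo")
        x, x_mu, x_nu, x_phi = _cart_and_partials(muin, nu, phi, self.dom.a)
        t_n = x_mu * muin_n[..., None] + x_nu * nu_n[..., None] \
            + x_phi * phi_n[..., None]
        t_p = x_mu * muin_p[..., None] + x_nu * nu_p[..., None] \
            + x_phi * phi_p[..., None]
        return x, t_n, t_p

    def endocardial_normal_element(self, q):
        """Unnormalized outward (cavity-exterior) normals v_nu0 x v_phi0
        at the endocardial quadrature nodes, with parametric weights."""
        x, t_n, t_p = self.endo_points_and_tangents(q)
        return np.cross(t_n, t_p), self._endo_w

    def _rim(self, q):
        """Deformed basal rim curve and its total phi0-derivative."""
        muin, muin_n, muin_p, nu, nu_n, nu_p, phi, phi_n, phi_p = \
            self._surface(q, "rim")
        x, x_mu, x_nu, x_phi = _cart_and_partials(muin, nu, phi, self.dom.a)
        dn = self._rim_dnu  # d nu_up0 / d phi0 along the rim
        dmu = muin_p + muin_n * dn
        dnu_ = nu_p + nu_n * dn
        dphi_ = phi_p + phi_n * dn
        dx = x_mu * dmu[..., None] + x_nu * dnu_[..., None] \
            + x_phi * dphi_[..., None]
        return x, dx

    # -- volume and sensitivities -------------------------------------------

    def cavity_volume(self, q):
        """Chamber volume V_lv (mL) at kinematic vector q (dtype-generic)."""
        x, t_n, t_p = self.endo_points_and_tangents(q)
        n = np.cross(t_n, t_p)
        V = np.sum(np.einsum("na,na->n", x, n) * self._endo_w) / 3.0

        rim, drim = self._rim(q)
        zc = rim[:, 2].mean()
        C = np.zeros(3, dtype=rim.dtype)
        C[2] = zc
        t_u = rim - C[None, :]                       # (n_phi, 3)
        # cap point P = C + u (rim - C); t_phi = u * drim; x.(t_u x t_phi)
        # is quadratic in u, integrated exactly by the radial Simpson rule
        cross_ut = np.cross(t_u, drim)               # (n_phi, 3)
        c0 = np.einsum("a,na->n", C, cross_ut)       # C . (t_u x drim)
        c1 = np.einsum("na,na->n", t_u, cross_ut)    # (rim-C) . (t_u x drim)
        u = self._ur
        cap = np.sum(
            (c0[None, :] * u[:, None] + c1[None, :] * u[:, None] ** 2)
            * self._w_ur[:, None] * self._rim_wphi[None, :]
        ) / 3.0
        return V + cap

    def volume_gradient(self, q):
        """eta = dV_lv/dq (mL per unit q), exact gradient of the discrete
        volume via complex step.  This is the vector used by the dynamics,
        which makes the pressure term energy-consistent by construction."""
        q = np.asarray(q, float)
        out = np.empty(q.size)
        for j in range(q.size):
            qc = q.astype(complex)
            qc[j] += 1j * _CS
            out[j] = np.imag(self.cavity_volume(qc)) / _CS
        return out

    def pressure_virtual_work(self, q):
        """eta by the direct surface-integral route: endocardial term
        int du/dq_i . (v_nu0 x v_phi0) plus the closing-cap term.  Agrees
        with ``volume_gradient`` to quadrature accuracy."""
        q = np.asarray(q, float)
        n_endo, w = self.endocardial_normal_element(q)
        rim, drim = self._rim(q)
        zc = rim[:, 2].mean()
        C = np.array([0.0, 0.0, zc])
        t_u = rim - C[None, :]
        u = self._ur

        out = np.empty(q.size)
        for j in range(q.size):
            qc = q.astype(complex)
            qc[j] += 1j * _CS
            xj, _, _ = self.endo_points_and_tangents(qc)
            du_endo = xj.imag / _CS
            out[j] = np.sum(np.einsum("na,na->n", du_endo, n_endo) * w)

            rim_j, drim_j = self._rim(qc)
            zc_j = rim_j[:, 2].mean()
            C_j = np.zeros(3, complex)
            C_j[2] = zc_j
            dC = C_j.imag / _CS
            drim_dq = rim_j.imag / _CS
            # cap normal at current q: (t_u x u drim); displacement rate of
            # the ruled point P(u) = C + u (rim - C)
            cross_ut = np.cross(t_u, drim)
            for ui, wu in zip(u, self._w_ur):
                dP = dC[None, :] + ui * (drim_dq - dC[None, :])
                out[j] += np.sum(
                    np.einsum("na,na->n", dP, ui * cross_ut)
                    * wu * self._rim_wphi)
        return out
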