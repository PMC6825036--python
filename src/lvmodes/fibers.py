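"""Myofiber architecture: helix-angle field and local (s, n, f) bases.

Cardiac muscle fibers wind helically around the ventricle, from a
left-handed helix at the epicardium to a right-handed one at the
endocardium.  Here the fiber direction ``e_f`` lies in the tangent plane of
the local constant-depth surface, at a helix angle ``alpha`` from the
circumferential direction that interpolates linearly in normalized
transmural depth between ``alpha_endo`` and ``alpha_epi`` (degrees,
Streeter-consistent defaults +60/-60).  The sheet axis ``e_s`` is the
outward transmural normal and ``e_n = e_f x e_s`` completes the
right-handed triad.  All bases are constructed in the reference
configuration, expressed in prolate physical components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError, ReferenceDomain, scale_factors

__all__ = ["FiberArchitecture", "fiber_basis", "rotate_tensor"]


@dataclass(frozen=True)
class FiberArchitecture:
    """Helix angles at the wall surfaces (degrees) with linear interpolation."""

    alpha_endo: float = 60.0
    alpha_epi: float = -60.0

    def __post_init__(self):
        for v in (self.alpha_endo, self.alpha_epi):
            if not -90.0 < v < 90.0:
                raise ValueError("helix angles must lie in (-90, 90) degrees")

    def alpha(self, depth):
        """Helix angle (radians) at normalized transmural depth in [0, 1]."""
        return np.deg2rad(
            self.alpha_endo + (self.alpha_epi - self.alpha_endo) * depth
        )


def fiber_basis(mu0, nu0, phi0, dom: ReferenceDomain,
                arch: FiberArchitecture = FiberArchitecture(),
                clamp_depth=True):
    """Local fiber/sheet/normal triad at reference wall points.

    Returns ``Q`` with shape (n, 3, 3): columns are (e_s, e_n, e_f) in
    prolate physical components, i.e. the rotation taking fiber-frame
    components to prolate components.

    The constant-depth surface through each point is ``mu_d(nu0, phi0) =
    mu_in0 + d (mu_out0 - mu_in0)`` at that point's depth d; its tangents
    (in prolate physical components, using the metric scale factors) give
    the in-surface circumferential and apex-base directions, and the
    surface normal gives ``e_s``.
    """
    mu0 = np.atleast_1d(np.asarray(mu0, float))
    nu0 = np.atleast_1d(np.asarray(nu0, float))
    phi0 = np.atleast_1d(np.asarray(phi0, float))
    g_mu, g_nu, g_phi = scale_factors(mu0, nu0, dom.a)
    if np.any(g_phi < 1e-12 * dom.a):
        raise GeometryError("fiber basis undefined on the axis (g_phi = 0)")

    m_in = np.asarray(dom.mu_in0(nu0, phi0))
    m_out = np.asarray(dom.mu_out0(nu0, phi0))
    thick = m_out - m_in
    depth = (mu0 - m_in) / thick
    if clamp_depth:
        depth = np.clip(depth, 0.0, 1.0)
    # unclamped depth extends the helix field smoothly past the wall
    # surfaces, which keeps the stress field differentiable there
    # partials of the constant-depth surface mu_d at fixed depth
    md_nu = np.asarray(dom.mu_in0(nu0, phi0, dnu=1)) * (1 - depth) \
        + np.asarray(dom.mu_out0(nu0, phi0, dnu=1)) * depth
    md_phi = np.asarray(dom.mu_in0(nu0, phi0, dphi=1)) * (1 - depth) \
        + np.asarray(dom.mu_out0(nu0, phi0, dphi=1)) * depth

    n = mu0.size
    t_nu = np.zeros((n, 3))
    t_nu[:, 0] = g_mu * md_nu
    t_nu[:, 1] = g_nu
    t_phi = np.zeros((n, 3))
    t_phi[:, 0] = g_mu * md_phi
    t_phi[:, 2] = g_phi

    e_s = np.cross(t_nu, t_phi)  # outward transmural normal (+mu component)
    e_s /= np.linalg.norm(e_s, axis=-1, keepdims=True)
    if np.any(e_s[:, 0] <= 0.0):
        raise GeometryError("transmural normal is not outward: bad surface slopes")
    # circumferential direction within the surface, orthonormal to e_s
    e_c = t_phi - np.sum(t_phi * e_s, axis=-1, keepdims=True) * e_s
    e_c /= np.linalg.norm(e_c, axis=-1, keepdims=True)
    # apex-to-base tangent completing the surface frame
    e_l = np.cross(e_s, e_c)
    e_l *= -np.sign(np.sum(e_l * t_nu, axis=-1, keepdims=True))  # -nu = toward base

    al = arch.alpha(depth)[:, None]
    e_f = np.cos(al) * e_c + np.sin(al) * e_l
    e_n = np.cross(e_f, e_s)
    return np.stack([e_s, e_n, e_f], axis=-1)


def rotate_tensor(S_fiber, Q):
    """Congruence transform S_prolate = Q S_fiber Q^T (batched)."""
    return Q @ S_fiber @ np.swapaxes(Q, -1, -2)
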