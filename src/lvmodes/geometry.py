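"""Prolate spheroidal geometry of the left-ventricular wall.

The unstressed myocardium is the region between an endocardial surface
``mu_in0(nu0, phi0)`` and an epicardial surface ``mu_out0(nu0, phi0)``,
bounded above by a basal curve ``nu_up0(phi0)`` and closed at the apex
``nu0 = pi``.  All three bounding functions are smooth splines, periodic in
the circumferential angle ``phi0``; ``a`` is the focal length of the
confocal ellipsoidal family (cm).

Coordinate convention: ``nu = pi`` is the apex (negative z), the base sits
at small ``nu``.  Physical lengths are centimetres, volumes cm^3 (mL).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, NdBSpline, make_interp_spline

__all__ = [
    "ProlateCoordinate",
    "prolate_to_cartesian",
    "cartesian_to_prolate",
    "scale_factors",
    "PeriodicSurfaceSpline",
    "BasalBoundaryCurve",
    "ReferenceDomain",
    "QuadratureGrid",
    "wall_volume",
    "make_fixture_geometry",
    "GeometryError",
]

#: offset keeping quadrature nodes off the apex coordinate singularity;
#: large enough that 1/sin(nu0)^2 cancellations stay well-conditioned,
#: small enough that the omitted apex strip (integrand ~ sin nu0) is
#: far below quadrature error
APEX_OFFSET = 1e-4


class GeometryError(ValueError):
    """Invalid geometric configuration (degenerate point, wall inversion...)."""


@dataclass(frozen=True)
class ProlateCoordinate:
    """A point (mu, nu, phi): mu >= 0, nu in [0, pi], phi wrapped to [0, 2pi)."""

    mu: float
    nu: float
    phi: float

    def __post_init__(self):
        if self.mu < 0:
            raise GeometryError(f"mu must be >= 0, got {self.mu}")
        if not 0.0 <= self.nu <= np.pi:
            raise GeometryError(f"nu must lie in [0, pi], got {self.nu}")
        object.__setattr__(self, "phi", float(np.mod(self.phi, 2.0 * np.pi)))


def prolate_to_cartesian(mu, nu, phi, a):
    """Map prolate spheroidal coordinates to Cartesian (x, y, z).

    x = a sinh(mu) sin(nu) cos(phi), y = a sinh(mu) sin(nu) sin(phi),
    z = a cosh(mu) cos(nu).  Accepts scalars or broadcastable arrays
    (real or complex, so the map can be differentiated by complex step).
    """
    sh, ch = np.sinh(mu), np.cosh(mu)
    sn, cn = np.sin(nu), np.cos(nu)
    return a * sh * sn * np.cos(phi), a * sh * sn * np.sin(phi), a * ch * cn


def cartesian_to_prolate(x, y, z, a):
    """Invert the prolate spheroidal map.

    Uses the focal-distance identities cosh(mu) = (r- + r+) / 2a and
    cos(nu) = (r- - r+) / 2a, with r+- the distances to the foci (0, 0, +-a).

    Raises
    ------
    GeometryError
        If the point lies on the focal segment mu = 0 where phi is undefined.
    """
    if a <= 0:
        raise GeometryError("focal length must be positive")
    rho2 = x * x + y * y
    rp = np.sqrt(rho2 + (z - a) ** 2)
    rm = np.sqrt(rho2 + (z + a) ** 2)
    ch = np.clip((rp + rm) / (2.0 * a), 1.0, None)
    cn = np.clip((rm - rp) / (2.0 * a), -1.0, 1.0)
    mu = np.arccosh(ch)
    nu = np.arccos(cn)
    # mu = 0 with nu strictly inside (0, pi) is the focal segment, where
    # the circumferential angle is undefined
    if np.any((mu < 1e-12) & (np.abs(cn) < 1.0 - 1e-12)):
        raise GeometryError("point on the focal segment: phi undefined")
    phi = np.mod(np.arctan2(y, x), 2.0 * np.pi)
    return mu, nu, phi


def scale_factors(mu, nu, a):
    """Metric scale factors (g_mu, g_nu, g_phi) of the prolate system.

    g_mu = g_nu = a sqrt(sinh^2 mu + sin^2 nu),  g_phi = a sinh(mu) sin(nu).
    """
    g = a * np.sqrt(np.sinh(mu) ** 2 + np.sin(nu) ** 2)
    return g, g, a * np.sinh(mu) * np.sin(nu)


def _natural_bc(values_shape_tail):
    zero = np.zeros(values_shape_tail)
    return ([(2, zero)], [(2, zero)])


class PeriodicSurfaceSpline:
    """Bicubic tensor-product spline surface ``mu(nu0, phi0)``.

    Natural end conditions in ``nu0``, periodic in ``phi0`` with period
    2 pi.  Built from control values sampled on a rectangular knot grid;
    the last ``phi0`` column wraps onto the first.  Control values at the
    apex row (``nu0 = pi``, if present) are averaged across ``phi0`` so the
    apex is a single point.
    """

    def __init__(self, nu_knots, phi_knots, values):
        nu_knots = np.asarray(nu_knots, float)
        phi_knots = np.asarray(phi_knots, float)
        values = np.array(values, float)
        if values.shape != (nu_knots.size, phi_knots.size):
            raise GeometryError("control-value grid does not match knots")
        if not np.isclose(phi_knots[0], 0.0) or not np.isclose(
            phi_knots[-1], 2.0 * np.pi
        ):
            raise GeometryError("phi knots must span [0, 2pi] inclusive")
        if np.isclose(nu_knots[-1], np.pi):
            values[-1, :] = values[-1, :].mean()
        values[:, -1] = values[:, 0]  # enforce the periodic wrap
        self.nu_knots = nu_knots
        self.phi_knots = phi_knots
        self.values = values
        b_phi = make_interp_spline(phi_knots, values.T, k=3, bc_type="periodic")
        b_nu = make_interp_spline(
            nu_knots, b_phi.c.T, k=3, bc_type=_natural_bc(b_phi.c.shape[:1])
        )
        self._nd = NdBSpline((b_nu.t, b_phi.t), b_nu.c, k=3)

    def __call__(self, nu0, phi0, dnu=0, dphi=0):
        """Evaluate the surface or a partial derivative d^dnu/dnu0 d^dphi/dphi0."""
        nu0 = np.asarray(nu0, float)
        phi0 = np.mod(np.asarray(phi0, float), 2.0 * np.pi)
        if np.any(nu0 < self.nu_knots[0] - 1e-12) or np.any(
            nu0 > self.nu_knots[-1] + 1e-12
        ):
            raise GeometryError("nu0 outside the surface parameter range")
        pts = np.stack(np.broadcast_arrays(nu0, phi0), axis=-1)
        out = self._nd(pts, nu=np.array([dnu, dphi]))
        return out if out.shape else float(out)

    def to_dict(self):
        return {
            "nu_knots": self.nu_knots.tolist(),
            "phi_knots": self.phi_knots.tolist(),
            "values": self.values.tolist(),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(d["nu_knots"], d["phi_knots"], d["values"])


class BasalBoundaryCurve:
    """One-dimensional periodic cubic spline ``nu_up0(phi0)``."""

    def __init__(self, phi_knots, values):
        phi_knots = np.asarray(phi_knots, float)
        values = np.array(values, float)
        if not np.isclose(phi_knots[0], 0.0) or not np.isclose(
            phi_knots[-1], 2.0 * np.pi
        ):
            raise GeometryError("phi knots must span [0, 2pi] inclusive")
        values[-1] = values[0]
        if np.any(values <= 0.0) or np.any(values >= np.pi):
            raise GeometryError("basal boundary must lie strictly inside (0, pi)")
        self.phi_knots = phi_knots
        self.values = values
        self._sp = CubicSpline(phi_knots, values, bc_type="periodic")

    def __call__(self, phi0, dphi=0):
        phi0 = np.mod(np.asarray(phi0, float), 2.0 * np.pi)
        out = self._sp(phi0, nu=dphi)
        return out if out.shape else float(out)

    def to_dict(self):
        return {"phi_knots": self.phi_knots.tolist(), "values": self.values.tolist()}

    @classmethod
    def from_dict(cls, d):
        return cls(d["phi_knots"], d["values"])


@dataclass
class ReferenceDomain:
    """The unstressed myocardial region Omega_0.

    Attributes
    ----------
    mu_in0, mu_out0 : PeriodicSurfaceSpline
        Endocardial and epicardial bounding surfaces.
    nu_up0 : BasalBoundaryCurve
        Basal boundary curve.
    a : float
        Focal length (cm).
    """

    mu_in0: PeriodicSurfaceSpline
    mu_out0: PeriodicSurfaceSpline
    nu_up0: BasalBoundaryCurve
    a: float

    def __post_init__(self):
        if self.a <= 0:
            raise GeometryError("focal length must be positive")
        self.validate()

    def validate(self, n_nu=41, n_phi=41):
        """Check mu_in0 < mu_out0 on a sample grid; raise on wall inversion."""
        phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
        for p in phi:
            nu = np.linspace(float(self.nu_up0(p)), np.pi, n_nu)
            if np.any(self.mu_in0(nu, np.full_like(nu, p)) >= self.mu_out0(nu, np.full_like(nu, p))):
                raise GeometryError("mu_in0 >= mu_out0 somewhere: wall inverted")

    def to_json(self, path=None):
        d = {
            "a": self.a,
            "mu_in0": self.mu_in0.to_dict(),
            "mu_out0": self.mu_out0.to_dict(),
            "nu_up0": self.nu_up0.to_dict(),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=1)
        return d

    @classmethod
    def from_json(cls, source):
        if isinstance(source, dict):
            d = source
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(
            PeriodicSurfaceSpline.from_dict(d["mu_in0"]),
            PeriodicSurfaceSpline.from_dict(d["mu_out0"]),
            BasalBoundaryCurve.from_dict(d["nu_up0"]),
            d["a"],
        )


def _simpson_weights(n):
    if n < 3 or n % 2 == 0:
        raise GeometryError("Simpson rule needs an odd node count >= 3")
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w / 3.0


def periodic_simpson_weights(n, period=2.0 * np.pi):
    """Composite Simpson weights on a periodic interval (n even, nodes at
    j * period / n; the wrap node absorbs both endpoint weights)."""
    if n < 4 or n % 2 == 1:
        raise GeometryError("periodic Simpson rule needs an even node count >= 4")
    h = period / n
    w = np.full(n, 2.0)
    w[1::2] = 4.0
    return w * h / 3.0


@dataclass
class QuadratureGrid:
    """Composite quadrature nodes over the parametric box of Omega_0.

    Composite Simpson's rule in all three directions: odd node counts in
    the transmural ``mu0`` and longitudinal ``nu0`` directions; in the
    periodic ``phi0`` direction the panels wrap around the seam, which
    requires an even node count (the two endpoint weights merge at the
    wrapped node).  Node coordinates and combined weights are stored
    flattened in C order over the (N_mu, N_nu, N_phi) axes.

    ``w_ref`` contains the full reference volume element, i.e. the
    parametric weight times g_mu0 g_nu0 g_phi0, so plain dots against
    ``w_ref`` integrate over Omega_0.
    """

    n_mu: int
    n_nu: int
    n_phi: int
    mu0: np.ndarray = field(repr=False)
    nu0: np.ndarray = field(repr=False)
    phi0: np.ndarray = field(repr=False)
    w_param: np.ndarray = field(repr=False)
    w_ref: np.ndarray = field(repr=False)
    shape: tuple = ()

    @classmethod
    def build(cls, dom: ReferenceDomain, n_mu=5, n_nu=21, n_phi=20):
        if n_mu % 2 == 0 or n_nu % 2 == 0:
            raise GeometryError("n_mu and n_nu must be odd for Simpson's rule")
        phi = np.arange(n_phi) * 2.0 * np.pi / n_phi
        w_phi = periodic_simpson_weights(n_phi)
        s_nu = np.linspace(0.0, 1.0, n_nu)
        w_nu_unit = _simpson_weights(n_nu) / (n_nu - 1)
        s_mu = np.linspace(0.0, 1.0, n_mu)
        w_mu_unit = _simpson_weights(n_mu) / (n_mu - 1)

        nu_lo = np.asarray(dom.nu_up0(phi))                  # (n_phi,)
        nu_hi = np.pi - APEX_OFFSET
        nu = nu_lo[None, :] + s_nu[:, None] * (nu_hi - nu_lo[None, :])  # (n_nu, n_phi)
        w_nu = w_nu_unit[:, None] * (nu_hi - nu_lo[None, :])

        nu_f = np.broadcast_to(nu, (n_mu, n_nu, n_phi))
        phi_f = np.broadcast_to(phi[None, None, :], (n_mu, n_nu, n_phi))
        m_in = np.asarray(dom.mu_in0(nu, np.broadcast_to(phi, nu.shape)))
        m_out = np.asarray(dom.mu_out0(nu, np.broadcast_to(phi, nu.shape)))
        mu = m_in[None] + s_mu[:, None, None] * (m_out - m_in)[None]
        w_mu = w_mu_unit[:, None, None] * (m_out - m_in)[None]

        w = w_mu * w_nu[None] * w_phi[None, None, :]
        g_mu0, _, g_phi0 = scale_factors(mu, nu_f, dom.a)
        w_ref = w * g_mu0 * g_mu0 * g_phi0
        return cls(
            n_mu=n_mu, n_nu=n_nu, n_phi=n_phi,
            mu0=mu.ravel(), nu0=nu_f.ravel().copy(), phi0=phi_f.ravel().copy(),
            w_param=w.ravel(), w_ref=w_ref.ravel(),
            shape=(n_mu, n_nu, n_phi),
        )


def wall_volume(dom: ReferenceDomain, grid: QuadratureGrid | None = None,
                n_mu=5, n_nu=21, n_phi=20):
    """Myocardial wall volume V_m (cm^3) by quadrature over Omega_0."""
    if grid is None:
        grid = QuadratureGrid.build(dom, n_mu=n_mu, n_nu=n_nu, n_phi=n_phi)
    return float(np.sum(grid.w_ref))


# ----------------------------------------------------------------------------
# fixture geometries

#: human-scale defaults: unloaded cavity in the ~100 mL class, ~1 cm wall
_FIXTURE = dict(a=4.4, mu_in=0.60, mu_out=0.82, nu_up=0.45 * np.pi)


def make_fixture_geometry(preset="axisymmetric", *, a=None, mu_in=None,
                          mu_out=None, nu_up=None, septal_amp=0.06,
                          basal_tilt=0.03, n_nu_knots=13, n_phi_knots=17):
    """Construct a human-scale truncated-ellipsoid LV reference domain.

    Presets
    -------
    ``axisymmetric``
        Confocal truncated ellipsoidal shell: constant mu_in0, mu_out0,
        nu_up0.
    ``asymmetric-septal``
        Perturbs the endocardial surface with a first circumferential
        harmonic (thicker "septal" wall near phi0 = 0, shaped to vanish at
        the apex) and tilts the basal curve with a sin(phi0) term.
    """
    if preset not in ("axisymmetric", "asymmetric-septal"):
        raise GeometryError(f"unknown preset {preset!r}")
    a = _FIXTURE["a"] if a is None else a
    mu_in = _FIXTURE["mu_in"] if mu_in is None else mu_in
    mu_out = _FIXTURE["mu_out"] if mu_out is None else mu_out
    nu_up = _FIXTURE["nu_up"] if nu_up is None else nu_up

    nu_k = np.linspace(nu_up - 0.05, np.pi, n_nu_knots)
    phi_k = np.linspace(0.0, 2.0 * np.pi, n_phi_knots)
    NN, PP = np.meshgrid(nu_k, phi_k, indexing="ij")

    vin = np.full_like(NN, mu_in)
    vup = np.full(phi_k.shape, nu_up)
    if preset == "asymmetric-septal":
        vin = mu_in - septal_amp * np.sin(NN) ** 2 * np.cos(PP)
        vup = nu_up + basal_tilt * np.sin(phi_k)
    vout = np.full_like(NN, mu_out)

    dom = ReferenceDomain(
        PeriodicSurfaceSpline(nu_k, phi_k, vin),
        PeriodicSurfaceSpline(nu_k, phi_k, vout),
        BasalBoundaryCurve(phi_k, vup),
        a,
    )
    return dom
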