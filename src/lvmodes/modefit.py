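"""Fitting deformation modes to sampled displacement fields.

Given a point-sampled 3D myocardial displacement field (in practice
derived from tagged-MRI registration; here also generated synthetically),
the kinematic variables are chosen to minimize the volume-averaged squared
displacement error

    O(q) = (1/V_m) int |u_m(x0; q) - u_r(x0)|^2 dV,

with ``u_m`` the model displacement of the material point ``x0``.  Rigid
body motion is removed from the target field first (weighted Procrustes
alignment).  The fit proceeds over a nested schedule of mode dictionaries,
warm-starting each fit from the previous one, and reports the mean
displacement error E(q; N) and the percentage of deformation accounted
for, 100 (E(0) - E(N)) / E(0).

Units: displacements and errors in mm (objective mm^2); reference point
coordinates are prolate (dimensionless / radians) with the focal length
carried by the domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .geometry import QuadratureGrid, ReferenceDomain
from .kinematics import CS_STEP, KinematicsEngine
from .modes import ModeBasisSpec, standard_basis

__all__ = [
    "DisplacementSampleSet",
    "synth_displacement_field",
    "remove_rigid_motion",
    "objective",
    "fit_modes",
    "FitResult",
    "default_schedule",
]


@dataclass
class DisplacementSampleSet:
    """Point-sampled displacement field over the reference wall.

    mu0, nu0, phi0 : reference prolate coordinates of the sample points.
    u : (n, 3) Cartesian displacements (mm).
    w : (n,) positive volume weights (their sum plays the role of V_m).
    """

    mu0: np.ndarray
    nu0: np.ndarray
    phi0: np.ndarray
    u: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        if np.any(self.w <= 0):
            raise ValueError("sample weights must be positive")
        if self.u.shape != (self.mu0.size, 3):
            raise ValueError("displacement array must be (n, 3)")


def synth_displacement_field(q_true, dom: ReferenceDomain,
                             basis: ModeBasisSpec, noise_mm=0.0, seed=0,
                             grid: QuadratureGrid | None = None
                             ) -> DisplacementSampleSet:
    """Mode-generated displacement field at quadrature nodes, plus optional
    isotropic Gaussian noise of standard deviation ``noise_mm`` per axis.

    A seeded synthetic stand-in for registration-derived displacement data.
    """
    if grid is None:
        grid = QuadratureGrid.build(dom)
    eng = KinematicsEngine(dom, basis, grid.mu0, grid.nu0, grid.phi0)
    u = (eng.positions(np.asarray(q_true, float))
         - eng.reference_positions()) * 10.0      # cm -> mm
    if noise_mm > 0.0:
        rng = np.random.default_rng(seed)
        u = u + rng.normal(0.0, noise_mm, size=u.shape)
    return DisplacementSampleSet(mu0=grid.mu0.copy(), nu0=grid.nu0.copy(),
                                 phi0=grid.phi0.copy(), u=u,
                                 w=grid.w_ref.copy())


def remove_rigid_motion(samples: DisplacementSampleSet, dom: ReferenceDomain
                        ) -> DisplacementSampleSet:
    """Remove the weighted least-squares rigid transform from the targets.

    Finds the rigid motion (R, t) minimizing sum w |R x0 + t - (x0 + u)|^2
    (weighted Kabsch) and replaces the targets by the residual displacements
    R^T (x0 + u - t) - x0, which never increases the weighted norm.
    """
    eng = KinematicsEngine(dom, standard_basis(1), samples.mu0, samples.nu0,
                           samples.phi0)
    x0 = eng.reference_positions() * 10.0
    y = x0 + samples.u
    w = samples.w / samples.w.sum()
    x_bar = w @ x0
    y_bar = w @ y
    H = (x0 - x_bar).T @ ((y - y_bar) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    if x0.shape[0] < 3 or np.linalg.matrix_rank(H) < 2:
        raise ValueError("degenerate point set: rigid alignment undefined")
    t = y_bar - R @ x_bar
    u_new = (y - t) @ R - x0
    return DisplacementSampleSet(mu0=samples.mu0, nu0=samples.nu0,
                                 phi0=samples.phi0, u=u_new, w=samples.w)


def _model_disp(engine, q):
    return (engine.positions(q) - engine.reference_positions()) * 10.0


def objective(q, samples: DisplacementSampleSet, engine: KinematicsEngine):
    """Volume-averaged squared displacement error O(q) (mm^2)."""
    r = _model_disp(engine, np.asarray(q, float)) - samples.u
    return float(np.sum(samples.w * np.sum(r * r, axis=-1)) / samples.w.sum())


def _objective_and_grad(q, samples, engine):
    q = np.asarray(q, float)
    wsum = samples.w.sum()
    r = _model_disp(engine, q) - samples.u
    O = float(np.sum(samples.w * np.sum(r * r, axis=-1)) / wsum)
    grad = np.empty(q.size)
    for j in range(q.size):
        qc = q.astype(complex)
        qc[j] += 1j * CS_STEP
        du = engine.positions(qc).imag / CS_STEP * 10.0
        grad[j] = 2.0 * np.sum(samples.w * np.sum(r * du, axis=-1)) / wsum
    return O, grad


def mean_error(q, samples: DisplacementSampleSet, engine):
    """Volume-averaged displacement error E(q; N) (mm)."""
    r = _model_disp(engine, np.asarray(q, float)) - samples.u
    return float(np.sum(samples.w * np.linalg.norm(r, axis=-1))
                 / samples.w.sum())


@dataclass
class FitResult:
    n_q: int
    q: np.ndarray
    objective: float       # mm^2
    mean_error: float      # mm, E(q; N)
    accounted_pct: float   # 100 (E0 - E) / E0
    success: bool
    message: str = ""


def default_schedule(n_max, start=3):
    """Nested dictionary sizes: the three uniform modes first, then one
    mode at a time alternating longitudinal/circumferential refinement
    across the blocks (the round-robin enumeration of the standard basis)."""
    return list(range(start, n_max + 1))


def _embed(q_small, basis_small: ModeBasisSpec, basis_big: ModeBasisSpec):
    q = np.zeros(basis_big.n_q)
    for block in ("mu", "nu", "phi"):
        small = basis_small.terms(block)
        big = list(basis_big.terms(block))
        off_s = basis_small.block_slices[block].start
        off_b = basis_big.block_slices[block].start
        for k, term in enumerate(small):
            q[off_b + big.index(term)] = q_small[off_s + k]
    return q


def _gauss_newton(samples, engine, q0, tol=1e-12, max_iter=60):
    """Damped Gauss-Newton on the weighted displacement residuals.

    The Jacobian is exact (complex step through the incompressibility
    solve); backtracking guards against inadmissible trial states.
    """
    sw = np.sqrt(samples.w / samples.w.sum())[:, None]
    nq = q0.size

    def residuals(q):
        with np.errstate(over="ignore", invalid="ignore"):
            r = (sw * (_model_disp(engine, q) - samples.u)).ravel()
        if not np.all(np.isfinite(r)):
            raise FloatingPointError("non-finite residual")
        return r

    q = q0.copy()
    r = residuals(q)
    for _ in range(max_iter):
        J = np.empty((r.size, nq))
        for j in range(nq):
            qc = q.astype(complex)
            qc[j] += 1j * CS_STEP
            with np.errstate(over="ignore", invalid="ignore"):
                du = engine.positions(qc).imag / CS_STEP * 10.0
            J[:, j] = (sw * du).ravel()
        dq, *_ = np.linalg.lstsq(J, -r, rcond=None)
        lam, r_new = 1.0, None
        while lam > 1e-8:
            try:
                r_new = residuals(q + lam * dq)
            except Exception:
                lam *= 0.5
                continue
            if r_new @ r_new < r @ r:
                break
            lam *= 0.5
        else:
            break  # no further decrease possible
        q = q + lam * dq
        step = float(np.max(np.abs(lam * dq)))
        r = r_new
        if step < tol:
            break
    gnorm = float(np.max(np.abs(J.T @ r)))
    converged = gnorm < 1e-8 * max(1.0, float(np.abs(J).max())
                                   * float(np.sqrt(r @ r)))
    return q, converged, float(r @ r)


def fit_modes(samples: DisplacementSampleSet, dom: ReferenceDomain,
              schedule=None, with_rigid_removal=True):
    """Fit nested mode dictionaries to a displacement field.

    Returns a list of FitResult, one per dictionary size in the schedule.
    Damped Gauss-Newton with exact mode-sensitivity Jacobians,
    warm-started from the previous (smaller) dictionary.  An optimizer
    failure is recorded and the schedule continues.
    """
    if schedule is None:
        schedule = default_schedule(12)
    if with_rigid_removal:
        samples = remove_rigid_motion(samples, dom)
    eng0 = KinematicsEngine(dom, standard_basis(1), samples.mu0,
                            samples.nu0, samples.phi0)
    E0 = mean_error(np.zeros(1), samples, eng0)

    results = []
    prev_q, prev_basis = None, None
    for n in schedule:
        basis = standard_basis(n)
        engine = KinematicsEngine(dom, basis, samples.mu0, samples.nu0,
                                  samples.phi0)
        starts = [np.zeros(n)]
        if prev_q is not None:
            starts.insert(0, _embed(prev_q, prev_basis, basis))
        best = None
        msg = ""
        for q0 in starts:   # warm start plus a cold restart from q = 0
            try:
                q_c, ok_c, rr = _gauss_newton(samples, engine, q0)
            except Exception as err:
                msg = str(err)
                continue
            if best is None or rr < best[2]:
                best = (q_c, ok_c, rr)
        if best is None:
            q, ok = starts[0], False
        else:
            q, ok = best[0], best[1]
        E = mean_error(q, samples, engine)
        results.append(FitResult(
            n_q=n, q=q, objective=objective(q, samples, engine),
            mean_error=E,
            accounted_pct=100.0 * (E0 - E) / E0 if E0 > 0 else 100.0,
            success=ok, message=msg))
        if ok or np.all(np.isfinite(q)):
            prev_q, prev_basis = q, basis
    return results
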