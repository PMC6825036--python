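"""Myocardial constitutive laws: passive elastic, viscous and active stress.

Passive elasticity follows the transversely isotropic exponential
(Guccione-type) strain-energy density

    Psi = (1/2) k_e (exp(W) - 1),
    W = b_ff E_ff^2 + b_xx (E_nn^2 + E_ss^2 + E_sn^2 + E_ns^2)
        + b_fx (E_sf^2 + E_fs^2 + E_nf^2 + E_fn^2),

with the Green strain expressed in the local fiber frame (s, n, f).  The
viscous second Piola-Kirchhoff stress is S_v = 2 k_v sum_j (C^-1 dE/dq_j
C^-1) dq_j/dt, and the active stress acts along the fiber direction with
tension T_a = A(t) g(lambda_ff) (k_a + k_av d(lambda_ff)/dt), combining a
modified-sine activation pulse, a Gaussian length-tension curve, and a
linear force-velocity dependence.

Stresses are in kPa; sarcomere lengths in micrometres; times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PassiveParams",
    "ActiveParams",
    "StressDecomposition",
    "strain_energy",
    "passive_pk2_fiber",
    "passive_pk2",
    "viscous_pk2",
    "activation",
    "length_tension",
    "active_pk2",
    "to_fiber_frame",
]


@dataclass(frozen=True)
class PassiveParams:
    """Passive elastic stiffness (kPa), exponents, and viscosity (kPa s).

    Defaults are package defaults in the physiological range reported for
    passive myocardium; they are not tied to any specific dataset.
    """

    k_e: float = 0.9
    b_ff: float = 18.5
    b_xx: float = 3.6
    b_fx: float = 1.6
    k_v: float = 0.05

    def __post_init__(self):
        if self.k_e <= 0:
            raise ValueError("k_e must be positive")
        if min(self.b_ff, self.b_xx, self.b_fx) < 0 or self.k_v < 0:
            raise ValueError("exponents and viscosity must be non-negative")


@dataclass(frozen=True)
class ActiveParams:
    """Active contraction parameters.

    k_a : peak isometric tension scale (kPa); k_av : force-velocity slope
    (kPa s); L_s0 / L_smax / L_sw : unstressed, optimal and width sarcomere
    lengths (um); d : activation pulse sharpness; T_act : activation
    duration (s); t_on : onset within the cycle (s).
    """

    k_a: float = 65.0
    k_av: float = 1.0
    L_s0: float = 1.95
    L_smax: float = 2.2
    L_sw: float = 0.42
    d: float = 2.0
    T_act: float = 0.30
    t_on: float = 0.45

    def __post_init__(self):
        if self.k_a < 0 or self.L_sw <= 0 or self.T_act <= 0 or self.d <= 0:
            raise ValueError("invalid active parameters")


def to_fiber_frame(E_prolate, Q):
    """Strain in fiber coordinates: E_fiber = Q^T E_prolate Q (batched)."""
    return np.swapaxes(Q, -1, -2) @ E_prolate @ Q


def _exp_w(E, p: PassiveParams):
    Ess, Enn, Eff = E[..., 0, 0], E[..., 1, 1], E[..., 2, 2]
    Esn, Esf, Enf = E[..., 0, 1], E[..., 0, 2], E[..., 1, 2]
    W = p.b_ff * Eff**2 + p.b_xx * (Enn**2 + Ess**2 + 2.0 * Esn**2) \
        + p.b_fx * 2.0 * (Esf**2 + Enf**2)
    return np.exp(W)


def strain_energy(E_fiber, p: PassiveParams):
    """Elastic strain-energy density Psi (kPa) from fiber-frame Green strain."""
    return 0.5 * p.k_e * (_exp_w(np.asarray(E_fiber), p) - 1.0)


def passive_pk2_fiber(E_fiber, p: PassiveParams):
    """Elastic PK2 stress dPsi/dE in the fiber frame (batched)."""
    E = np.asarray(E_fiber)
    ew = _exp_w(E, p)[..., None, None]
    b = np.array([
        [p.b_xx, p.b_xx, p.b_fx],
        [p.b_xx, p.b_xx, p.b_fx],
        [p.b_fx, p.b_fx, p.b_ff],
    ])
    return p.k_e * ew * b * E


def passive_pk2(E_fiber, p: PassiveParams, Q):
    """Elastic PK2 stress rotated to prolate components."""
    S = passive_pk2_fiber(E_fiber, p)
    return Q @ S @ np.swapaxes(Q, -1, -2)


def viscous_pk2(C, dE_dq, qdot, k_v):
    """Per-mode viscous PK2 matrices and their qdot-weighted sum.

    Parameters
    ----------
    C : (n, 3, 3) right Cauchy-Green tensor.
    dE_dq : (N_q, n, 3, 3) Green-strain sensitivities.
    qdot : (N_q,) rates, or None to return only the per-mode matrices.

    Returns (S_vq, S_v) with S_vq of shape (N_q, n, 3, 3).
    """
    Ci = np.linalg.inv(C)
    S_vq = 2.0 * k_v * (Ci[None] @ dE_dq @ Ci[None])
    S_v = None
    if qdot is not None:
        S_v = np.einsum("j,jnab->nab", np.asarray(qdot, float), S_vq)
    return S_vq, S_v


def activation(t, ap: ActiveParams):
    """Modified-sine activation A(t) in [0, 1]."""
    tau = np.asarray(t, float) - ap.t_on
    inside = (tau >= 0.0) & (tau <= ap.T_act)
    out = np.where(inside, np.sin(np.pi * np.clip(tau, 0, ap.T_act) / ap.T_act)
                   ** ap.d, 0.0)
    return out if out.shape else float(out)


def length_tension(lam_ff, ap: ActiveParams):
    """Gaussian length-tension factor g(lambda_ff) in (0, 1]."""
    ls = ap.L_s0 * np.asarray(lam_ff)
    return np.exp(-((ls - ap.L_smax) ** 2) / (2.0 * ap.L_sw) ** 2)


def active_pk2(t, lam_ff, dlam_dq, ap: ActiveParams, Q):
    """Active PK2 stress split into rate-independent and per-mode rate parts.

    Returns (S_a0, S_aq): the fiber tension k_a A g along e_f x e_f, and
    per-mode matrices k_av A g (dlambda_ff/dq_j) e_f x e_f (prolate frame),
    so the full active stress is S_a0 + sum_j S_aq[j] qdot_j.
    """
    A = activation(t, ap)
    g = length_tension(lam_ff, ap)
    ef = Q[..., :, 2]
    ff = ef[..., :, None] * ef[..., None, :]       # (n, 3, 3) e_f outer e_f
    S_a0 = (ap.k_a * A * g)[..., None, None] * ff
    S_aq = (ap.k_av * A * g)[None, ..., None, None] * dlam_dq[..., None, None] * ff[None]
    return S_a0, S_aq


@dataclass
class StressDecomposition:
    """Total PK2 stress split for the ODE assembly:
    S = S_e + S_a0 + sum_j (S_aq[j] + S_vq[j]) qdot_j  (prolate frame)."""

    S_e: np.ndarray
    S_a0: np.ndarray
    S_aq: np.ndarray
    S_vq: np.ndarray

    def total(self, qdot):
        qdot = np.asarray(qdot, float)
        return self.S_e + self.S_a0 + np.einsum(
            "j,jnab->nab", qdot, self.S_aq + self.S_vq)
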