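"""Fourier deformation-mode dictionary.

Each global deformation mode displaces one prolate coordinate field
(endocardial ``mu_in``, longitudinal ``nu`` or circumferential ``phi``) by a
separable basis function

    f(nu0, phi0) = [1 - cos((i + 1)(nu0 - pi))] * {cos(m phi0) | sin(m phi0)}

whose amplitude is one kinematic variable ``q``.  The modified-cosine
longitudinal factor vanishes (with zero slope) at the apex ``nu0 = pi``, so
every mode leaves the apex fixed; cosine terms with ``m = 0`` generate
axisymmetric deformations.

The global ordering of the kinematic vector ``q`` is block-contiguous:
first all mu-terms, then all nu-terms, then all phi-terms.  Within a block,
terms are enumerated by increasing total resolution level ``s = i + m``;
inside a level, by decreasing ``i``, with the cosine term preceding the
sine term of the same (i, m).  This ordering is part of every serialized
result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModeTerm", "ModeBasisSpec", "standard_basis", "mode_shape"]

BLOCKS = ("mu", "nu", "phi")


@dataclass(frozen=True)
class ModeTerm:
    """One separable Fourier term: longitudinal order ``i`` >= 0,
    circumferential harmonic ``m`` (>= 1 for sine, >= 0 for cosine)."""

    i: int
    m: int
    kind: str  # "cos" | "sin"

    def __post_init__(self):
        if self.kind not in ("cos", "sin"):
            raise ValueError(f"kind must be 'cos' or 'sin', got {self.kind!r}")
        if self.i < 0 or self.m < 0 or (self.kind == "sin" and self.m < 1):
            raise ValueError(f"invalid term indices {self}")

    def to_list(self):
        return [self.i, self.m, self.kind]


def _block_term_sequence():
    """Canonical per-block term enumeration, by resolution level s = i + m."""
    s = 0
    while True:
        for i in range(s, -1, -1):
            m = s - i
            if m == 0:
                yield ModeTerm(i, 0, "cos")
            else:
                yield ModeTerm(i, m, "cos")
                yield ModeTerm(i, m, "sin")
        s += 1


def _first_terms(n):
    gen = _block_term_sequence()
    return tuple(next(gen) for _ in range(n))


@dataclass(frozen=True)
class ModeBasisSpec:
    """Ordered mode dictionary for the three displaced coordinates."""

    mu_terms: tuple
    nu_terms: tuple
    phi_terms: tuple

    @property
    def n_q(self):
        return len(self.mu_terms) + len(self.nu_terms) + len(self.phi_terms)

    @property
    def block_slices(self):
        n1, n2 = len(self.mu_terms), len(self.nu_terms)
        return {
            "mu": slice(0, n1),
            "nu": slice(n1, n1 + n2),
            "phi": slice(n1 + n2, self.n_q),
        }

    def terms(self, block):
        return {"mu": self.mu_terms, "nu": self.nu_terms, "phi": self.phi_terms}[block]

    def ordering(self):
        """Serializable description of the global q ordering."""
        out = []
        for block in BLOCKS:
            out.extend([block] + t.to_list() for t in self.terms(block))
        return out

    def to_dict(self):
        return {
            "mu": [t.to_list() for t in self.mu_terms],
            "nu": [t.to_list() for t in self.nu_terms],
            "phi": [t.to_list() for t in self.phi_terms],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            tuple(ModeTerm(i, m, k) for i, m, k in d["mu"]),
            tuple(ModeTerm(i, m, k) for i, m, k in d["nu"]),
            tuple(ModeTerm(i, m, k) for i, m, k in d["phi"]),
        )


def standard_basis(n_q) -> ModeBasisSpec:
    """Default dictionary with ``n_q`` modes.

    Term slots are allocated round-robin over the blocks in the order
    (mu, phi, nu) — so the three leading modes are uniform expansion,
    uniform torsion and uniform shortening — while the q vector itself
    stays block-contiguous in the order (mu, nu, phi).
    """
    if n_q < 1:
        raise ValueError("n_q must be >= 1")
    counts = {"mu": 0, "phi": 0, "nu": 0}
    order = ("mu", "phi", "nu")
    for k in range(n_q):
        counts[order[k % 3]] += 1
    return ModeBasisSpec(
        mu_terms=_first_terms(counts["mu"]),
        nu_terms=_first_terms(counts["nu"]),
        phi_terms=_first_terms(counts["phi"]),
    )


def _long_factor(term, nu0, d):
    """Longitudinal factor 1 - cos[(i+1)(nu0 - pi)] or its nu0-derivative."""
    k = term.i + 1
    arg = k * (nu0 - np.pi)
    if d == 0:
        return 1.0 - np.cos(arg)
    if d == 1:
        return k * np.sin(arg)
    if d == 2:
        return k * k * np.cos(arg)
    raise ValueError("derivative order up to 2")


def _circ_factor(term, phi0, d):
    m = term.m
    if term.kind == "cos":
        f = [np.cos, lambda x: -np.sin(x), lambda x: -np.cos(x)][d]
    else:
        f = [np.sin, np.cos, lambda x: -np.sin(x)][d]
    return (m**d) * f(m * phi0)


def basis_matrix(terms, nu0, phi0, dnu=0, dphi=0):
    """Matrix ``B`` with ``B[p, t]`` = derivative of term t at point p, so
    that a displacement-field derivative is the product ``B @ q_block``."""
    nu0 = np.atleast_1d(np.asarray(nu0, float))
    phi0 = np.atleast_1d(np.asarray(phi0, float))
    cols = [
        _long_factor(t, nu0, dnu) * _circ_factor(t, phi0, dphi) for t in terms
    ]
    if not cols:
        return np.zeros((nu0.size, 0))
    return np.stack(cols, axis=-1)


def mode_shape(nu0, phi0, terms, coeffs):
    """Displacement value and first partials of one block's mode sum.

    Returns (f, df_dnu0, df_dphi0) evaluated pointwise.
    """
    coeffs = np.asarray(coeffs)
    if coeffs.shape[-1] != len(terms):
        raise ValueError("coefficient count does not match the term list")
    val = basis_matrix(terms, nu0, phi0) @ coeffs
    dnu = basis_matrix(terms, nu0, phi0, dnu=1) @ coeffs
    dphi = basis_matrix(terms, nu0, phi0, dphi=1) @ coeffs
    return val, dnu, dphi
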