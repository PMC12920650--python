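"""Normalized Legendre polynomial bases of standardized age.

Ages are mapped affinely from an analysis window (default 1-18 years) onto
[-1, 1], on which the scaled Legendre polynomials

    phi_j(m) = sqrt((2j + 1) / 2) * P_j(m),   j = 0, 1, ...

form an orthonormal system: the integral of phi_i * phi_j over [-1, 1] is
the Kronecker delta.  Every other module expresses trajectories on this
basis, so random-regression coefficient covariances translate to smooth
covariance functions of age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as _npleg

__all__ = [
    "AgeStandardizer",
    "LegendreCoefficients",
    "BasisMatrix",
    "standardize_age",
    "lambda_matrix",
    "basis_matrix",
]


@dataclass(frozen=True)
class AgeStandardizer:
    """Affine map from an age window onto the interval [-1, 1].

    ``min_age`` maps to -1 and ``max_age`` to +1.  The map is strictly
    increasing and exactly invertible.
    """

    min_age: float = 1.0
    max_age: float = 18.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.min_age) and np.isfinite(self.max_age)):
            raise ValueError("age bounds must be finite")
        if self.min_age >= self.max_age:
            raise ValueError(
                f"min_age ({self.min_age}) must be strictly below max_age ({self.max_age})"
            )

    def standardize(self, age):
        """Map ages in years to standardized ages in [-1, 1]."""
        age = np.asarray(age, dtype=float)
        if not np.all(np.isfinite(age)):
            raise ValueError("non-finite age encountered")
        return -1.0 + 2.0 * (age - self.min_age) / (self.max_age - self.min_age)

    def unstandardize(self, m):
        """Inverse map: standardized age back to years."""
        m = np.asarray(m, dtype=float)
        return self.min_age + (np.asarray(m) + 1.0) * (self.max_age - self.min_age) / 2.0


def standardize_age(age, standardizer: AgeStandardizer | None = None):
    """Standardize ``age`` (years) to [-1, 1] using ``standardizer``.

    Out-of-range ages are mapped affinely without clipping; filtering to the
    analysis window is the caller's responsibility.
    """
    if standardizer is None:
        standardizer = AgeStandardizer()
    return standardizer.standardize(age)


@dataclass(frozen=True)
class LegendreCoefficients:
    """Monomial coefficients of the scaled Legendre polynomials.

    ``coeff`` is a k x k upper-triangular-by-parity matrix whose column j
    holds the coefficients of m^0 ... m^(k-1) for the scaled Legendre
    polynomial of degree j.  Entries whose row parity differs from the
    column parity are exactly zero.
    """

    order: int
    coeff: np.ndarray

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.coeff.shape != (self.order, self.order):
            raise ValueError("coefficient matrix shape does not match order")


def lambda_matrix(k: int) -> LegendreCoefficients:
    """Build the k x k scaled Legendre coefficient matrix.

    Column j (0-based) contains sqrt((2j + 1)/2) times the monomial
    coefficients of the degree-j Legendre polynomial, computed from the
    standard recurrence via :mod:`numpy.polynomial.legendre`.  Deterministic
    and exact to floating point; no table lookup.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    coeff = np.zeros((k, k))
    for j in range(k):
        e = np.zeros(j + 1)
        e[j] = 1.0
        poly = _npleg.leg2poly(e)  # monomial coefficients of P_j
        coeff[: j + 1, j] = np.sqrt((2 * j + 1) / 2.0) * poly
    return LegendreCoefficients(order=k, coeff=coeff)


@dataclass(frozen=True)
class BasisMatrix:
    """Scaled Legendre polynomials evaluated at standardized ages.

    ``values`` is t x k with row r holding phi_0(m_r) ... phi_(k-1)(m_r).
    """

    ages_std: np.ndarray
    order: int
    values: np.ndarray


def basis_matrix(ages_std, k: int) -> BasisMatrix:
    """Evaluate the k scaled Legendre polynomials at standardized ages.

    Computes Phi = M Lambda where M is the Vandermonde matrix of powers
    m^0 ... m^(k-1) and Lambda is :func:`lambda_matrix`.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    m = np.atleast_1d(np.asarray(ages_std, dtype=float))
    if m.size == 0:
        raise ValueError("empty age vector")
    if np.any(np.abs(m) > 1.0 + 1e-12):
        raise ValueError("standardized ages must lie in [-1, 1]")
    M = np.vander(m, N=k, increasing=True)
    lam = lambda_matrix(k)
    return BasisMatrix(ages_std=m, order=k, values=M @ lam.coeff)
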