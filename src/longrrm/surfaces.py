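"""Age-scale variance, heritability and correlation surfaces with delta-method SEs.

Coefficient-scale covariance matrices K estimated on the Legendre basis are
mapped to the observed age scale as Phi K Phi' for a basis matrix Phi
evaluated on an age grid.  Because the covariance function is continuous in
age, values at shared ages do not depend on the grid used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from longrrm.basis import AgeStandardizer, BasisMatrix, basis_matrix
from longrrm.reml import RRMFit, VarianceParams

__all__ = [
    "AgeScaleSurfaces",
    "covariance_surface",
    "heritability_curve",
    "correlation_surface",
    "delta_method_se",
    "compute_surfaces",
]


def covariance_surface(K: np.ndarray, Phi: BasisMatrix) -> np.ndarray:
    """Transform a coefficient covariance K to the age scale: Phi K Phi'."""
    K = np.asarray(K, dtype=float)
    if K.shape[0] != Phi.order:
        raise ValueError("covariance order does not match the basis order")
    V = Phi.values @ K @ Phi.values.T
    return (V + V.T) / 2.0


def heritability_curve(Vg: np.ndarray, Vi: np.ndarray, sigma2_e) -> np.ndarray:
    """Pointwise heritability diag(Vg) / (diag(Vg) + diag(Vi) + sigma2_e).

    ``sigma2_e`` may be a scalar or a per-age vector (heterogeneous model).
    """
    vg = np.diag(np.asarray(Vg, dtype=float))
    vi = np.diag(np.asarray(Vi, dtype=float))
    vp = vg + vi + np.asarray(sigma2_e, dtype=float)
    if np.any(vp <= 0):
        raise ValueError("zero phenotypic variance on the grid")
    return vg / vp


def correlation_surface(V: np.ndarray) -> np.ndarray:
    """Correlation matrix V(t1,t2) / sqrt(V(t1,t1) V(t2,t2))."""
    d = np.diag(V)
    if np.any(d <= 0):
        raise ValueError("non-positive diagonal in covariance surface")
    s = np.sqrt(d)
    R = V / np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    return R


def delta_method_se(func, theta: np.ndarray, sampling_cov: np.ndarray, rel_step: float = 1e-6) -> float:
    """Delta-method SE of a scalar function of the variance parameters.

    The gradient is taken by central differences with a relative step of
    ``rel_step`` per coordinate (absolute fallback for zero coordinates).
    """
    theta = np.asarray(theta, dtype=float)
    grad = np.empty_like(theta)
    for j in range(theta.size):
        h = rel_step * max(abs(theta[j]), 1e-8)
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        grad[j] = (func(up) - func(dn)) / (2.0 * h)
    if not np.all(np.isfinite(grad)):
        raise ValueError("non-finite gradient in delta method")
    var = float(grad @ sampling_cov @ grad)
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class AgeScaleSurfaces:
    """Variance components and derived quantities on an age grid, with SEs."""

    ages: np.ndarray
    Vg: np.ndarray
    Vi: np.ndarray
    Vp: np.ndarray
    h2: np.ndarray
    rg: np.ndarray
    rp: np.ndarray
    se_Vg: np.ndarray
    se_Vi: np.ndarray
    se_h2: np.ndarray
    se_rg: np.ndarray
    se_rp: np.ndarray


def _sigma_per_age(sigma2_e: np.ndarray, ages: np.ndarray, standardizer: AgeStandardizer) -> np.ndarray:
    """Residual variance at each grid age; per-year bins use the bin value."""
    if sigma2_e.size == 1:
        return np.full(ages.size, float(sigma2_e[0]))
    lo = int(np.floor(standardizer.min_age))
    idx = np.clip(np.floor(ages).astype(int) - lo, 0, sigma2_e.size - 1)
    return sigma2_e[idx]


def compute_surfaces(
    fit: RRMFit,
    ages=None,
    with_se: bool = True,
) -> AgeScaleSurfaces:
    """All age-scale surfaces from a fit, default 18 yearly grid points.

    The residual variance enters the phenotypic covariance on the diagonal
    only (measurement errors at distinct ages are independent), so phenotypic
    correlations between distinct ages stay strictly below one whenever the
    residual variance is positive.
    """
    std = fit.standardizer
    if ages is None:
        ages = np.linspace(std.min_age, std.max_age, 18)
    ages = np.asarray(ages, dtype=float)
    kg, ki = fit.spec.k_g, fit.spec.k_i
    nb = len(fit.varparams.sigma2_e)
    theta = fit.varparams.pack()

    def surfaces_of(vec):
        vp = VarianceParams.unpack(vec, kg, ki, nb)
        Phi_g = basis_matrix(std.standardize(ages), kg) if kg else None
        Phi_i = basis_matrix(std.standardize(ages), ki) if ki else None
        Vg = covariance_surface(vp.Kg, Phi_g) if kg else np.zeros((ages.size, ages.size))
        Vi = covariance_surface(vp.Ki, Phi_i) if ki else np.zeros((ages.size, ages.size))
        sig = _sigma_per_age(vp.sigma2_e, ages, std)
        Vp = Vg + Vi + np.diag(sig)
        return Vg, Vi, Vp

    Vg, Vi, Vp = surfaces_of(theta)
    sig = _sigma_per_age(fit.varparams.sigma2_e, ages, std)
    h2 = heritability_curve(Vg, Vi, sig)
    rg = correlation_surface(Vg) if kg else np.full_like(Vg, np.nan)
    rp = correlation_surface(Vp)

    t = ages.size
    se_Vg = np.zeros((t, t))
    se_Vi = np.zeros((t, t))
    se_h2 = np.zeros(t)
    se_rg = np.zeros((t, t))
    se_rp = np.zeros((t, t))
    if with_se:
        S = fit.sampling_cov
        for a in range(t):
            se_h2[a] = delta_method_se(
                lambda v, a=a: _h2_at(v, a, surfaces_of), theta, S
            )
            for b in range(a, t):
                se_Vg[a, b] = se_Vg[b, a] = delta_method_se(
                    lambda v, a=a, b=b: surfaces_of(v)[0][a, b], theta, S
                )
                se_Vi[a, b] = se_Vi[b, a] = delta_method_se(
                    lambda v, a=a, b=b: surfaces_of(v)[1][a, b], theta, S
                )
                if a != b:
                    if kg:
                        se_rg[a, b] = se_rg[b, a] = delta_method_se(
                            lambda v, a=a, b=b: _corr_at(v, a, b, surfaces_of, 0), theta, S
                        )
                    se_rp[a, b] = se_rp[b, a] = delta_method_se(
                        lambda v, a=a, b=b: _corr_at(v, a, b, surfaces_of, 2), theta, S
                    )
    return AgeScaleSurfaces(
        ages=ages, Vg=Vg, Vi=Vi, Vp=Vp, h2=h2, rg=rg, rp=rp,
        se_Vg=se_Vg, se_Vi=se_Vi, se_h2=se_h2, se_rg=se_rg, se_rp=se_rp,
    )


def _h2_at(vec, a, surfaces_of):
    Vg, Vi, Vp = surfaces_of(vec)
    return Vg[a, a] / Vp[a, a]


def _corr_at(vec, a, b, surfaces_of, which):
    V = surfaces_of(vec)[which]
    return V[a, b] / np.sqrt(V[a, a] * V[b, b])
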