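"""Eigen-analysis of the genetic coefficient covariance matrix.

Principal components of Kg are orthogonal axes of genetic variation across
age; eigenvectors are mapped to eigenfunctions of standardized age through
the Legendre coefficient matrix.  Includes the chi-square test for the
variance attributable to trailing components, simulation-based confidence
intervals for eigenvalue shares, and per-individual PC polygenic scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2

from longrrm._linalg import vech, unvech
from longrrm.basis import lambda_matrix, basis_matrix

__all__ = [
    "GeneticPCA",
    "PCPolygenicScores",
    "decompose",
    "eigenfunctions",
    "variance_share_test",
    "eigenvalue_ci",
    "pc_polygenic_scores",
]


@dataclass
class GeneticPCA:
    E: np.ndarray  # orthonormal eigenvectors, columns in descending eigenvalue order
    D: np.ndarray  # eigenvalues, descending
    shares: np.ndarray  # D / sum(D) after flooring negatives at zero


def decompose(Kg: np.ndarray) -> GeneticPCA:
    """Eigendecompose Kg = E D E' with a reproducible sign convention.

    Eigenvalues are returned in descending order; each eigenvector is flipped
    so its largest-magnitude entry is positive.  Negative eigenvalues (which
    can arise when Kg is reconstructed from rounded estimates) are floored at
    zero for the variance shares, with a warning.
    """
    Kg = np.asarray(Kg, dtype=float)
    if not np.allclose(Kg, Kg.T, atol=1e-10):
        raise ValueError("Kg must be symmetric")
    w, V = np.linalg.eigh((Kg + Kg.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    wpos = w.copy()
    if np.any(w < 0):
        warnings.warn("negative eigenvalues floored at zero for variance shares")
        wpos = np.clip(w, 0.0, None)
    return GeneticPCA(E=V, D=w, shares=wpos / wpos.sum())


def eigenfunctions(E: np.ndarray, lam=None):
    """Eigenfunction coefficients Lambda E and a pointwise evaluator.

    Column j of the returned matrix holds the monomial coefficients (powers
    of standardized age) of the j-th eigenfunction.  The evaluator maps
    (m, j) -> psi_j(m) for m in [-1, 1].
    """
    E = np.asarray(E, dtype=float)
    k = E.shape[0]
    if lam is None:
        lam = lambda_matrix(k)
    if lam.order != k:
        raise ValueError("Legendre coefficient order does not match eigenvectors")
    coeff = lam.coeff @ E

    def evaluate(m, j):
        m = np.asarray(m, dtype=float)
        powers = np.vander(np.atleast_1d(m), N=k, increasing=True)
        out = powers @ coeff[:, j]
        return out if np.ndim(m) else float(out[0])

    return coeff, evaluate


def variance_share_test(Kg: np.ndarray, sampling_cov: np.ndarray, q: int) -> dict:
    """Chi-square test that the q smallest eigenvalues of Kg are zero.

    Builds the reduced matrix Kg* with the q trailing eigenvalues zeroed and
    forms the quadratic statistic vech(Kg - Kg*)' S^-1 vech(Kg - Kg*) against
    a chi-square with q(q+1)/2 degrees of freedom.  ``sampling_cov`` must be
    over the diagonal-major vech of Kg.
    """
    Kg = np.asarray(Kg, dtype=float)
    k = Kg.shape[0]
    if not (1 <= q < k):
        raise ValueError("q must satisfy 1 <= q < k_g")
    nv = k * (k + 1) // 2
    S = np.asarray(sampling_cov, dtype=float)
    if S.shape != (nv, nv):
        raise ValueError("sampling covariance has wrong dimension for vech(Kg)")
    w, V = np.linalg.eigh((Kg + Kg.T) / 2.0)
    # w ascending: zero the q smallest
    wstar = w.copy()
    wstar[:q] = 0.0
    Kstar = (V * wstar) @ V.T
    d = vech(Kg) - vech(Kstar)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        warnings.warn("singular sampling covariance; using pseudo-inverse")
        Sinv = np.linalg.pinv(S)
    stat = float(d @ Sinv @ d)
    df = q * (q + 1) // 2
    return {"chi2": stat, "df": df, "p": float(_chi2.sf(stat, df))}


def eigenvalue_ci(
    Kg: np.ndarray,
    sampling_cov: np.ndarray,
    n_sim: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    project_psd: bool = False,
) -> dict:
    """Simulation confidence intervals for eigenvalues and variance shares.

    Draws vech vectors from MVN(vech(Kg), S), rebuilds symmetric matrices and
    eigendecomposes them.  Non-PSD draws are discarded by default (counted in
    the output); with ``project_psd`` they are projected onto the PSD cone
    instead.  Errors out if more than half of the draws are non-PSD.
    """
    Kg = np.asarray(Kg, dtype=float)
    k = Kg.shape[0]
    rng = np.random.default_rng(seed)
    mu = vech(Kg)
    draws = rng.multivariate_normal(mu, sampling_cov, size=n_sim, method="svd")
    eigs, shares = [], []
    n_bad = 0
    for v in draws:
        K = unvech(v, k)
        w = np.sort(np.linalg.eigvalsh(K))[::-1]
        if w[-1] < 0:
            n_bad += 1
            if not project_psd:
                continue
            w = np.clip(w, 0.0, None)
        if w.sum() <= 0:
            continue
        eigs.append(w)
        shares.append(w / w.sum())
    if not project_psd and n_bad > n_sim / 2:
        raise ValueError(
            "more than half of the simulated matrices were non-PSD; "
            "reduce parameter uncertainty or use project_psd=True"
        )
    eigs = np.asarray(eigs)
    shares = np.asarray(shares)
    a = (1.0 - level) / 2.0
    return {
        "eigenvalue_ci": np.quantile(eigs, [a, 1.0 - a], axis=0).T,
        "share_ci": np.quantile(shares, [a, 1.0 - a], axis=0).T,
        "n_nonpsd": n_bad,
        "n_used": len(eigs),
    }


@dataclass
class PCPolygenicScores:
    scores: np.ndarray  # N x k, per-individual score on each PC
    strata: np.ndarray  # N x k array of {"low", "average", "high"}
    ids: list


def pc_polygenic_scores(blup_g: np.ndarray, E: np.ndarray, ids=None) -> PCPolygenicScores:
    """Per-individual PC scores G = alpha_hat E with +/- 1 SD strata.

    For each PC, individuals more than one SD below (above) the mean score
    are labelled "low" ("high"); the rest "average".
    """
    alpha = np.asarray(blup_g, dtype=float)
    if alpha.size == 0 or alpha.shape[0] == 0:
        raise ValueError("empty BLUP matrix")
    if alpha.shape[1] != E.shape[0]:
        raise ValueError("BLUP column count does not match eigenvector order")
    G = alpha @ E
    mu = G.mean(axis=0)
    sd = G.std(axis=0, ddof=1)
    strata = np.full(G.shape, "average", dtype=object)
    strata[G < mu - sd] = "low"
    strata[G > mu + sd] = "high"
    if ids is None:
        ids = list(range(alpha.shape[0]))
    return PCPolygenicScores(scores=G, strata=strata, ids=list(ids))


def stratum_mean_trajectories(
    pcs: PCPolygenicScores,
    blup_g: np.ndarray,
    ages_std: np.ndarray,
    component: int = 0,
) -> dict:
    """Mean genetic trajectory phi(m)' mean(alpha) per stratum of one PC."""
    k = blup_g.shape[1]
    Phi = basis_matrix(ages_std, k).values
    out = {}
    for label in ("low", "average", "high"):
        mask = pcs.strata[:, component] == label
        if mask.any():
            out[label] = Phi @ blup_g[mask].mean(axis=0)
    return out
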