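"""AI-REML for random regression models with genomic relationship structure.

The model for a vector of longitudinal records y is

    y = X b + Z_g g + Z_i i + e,
    var(g) = A (x) Kg,   var(i) = I_N (x) Ki,   var(e) = R

with A an N x N genomic relationship matrix, Kg / Ki small coefficient
covariance matrices on an orthonormal Legendre basis of standardized age, and
R diagonal (one residual variance, or one per yearly age bin).

Estimation uses Henderson's mixed-model equations.  The individual-effect
block is block-diagonal per individual and absorbed by Schur complement, so
only the reduced system over fixed effects and genetic coefficients is
factorized.  A handful of EM-REML warm-up iterations is followed by
average-information Newton steps taken in Cholesky/log coordinates (PSD by
construction) with step-halving so the restricted likelihood never
decreases.  The sampling covariance of the variance parameters is the
inverse of the average information at the optimum, ordered as vech(Kg),
vech(Ki), residual terms (diagonal-major vech, see :mod:`longrrm._linalg`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import lapack
from scipy.stats import chi2 as _chi2

from longrrm._linalg import vech, unvech, vech_indices
from longrrm.basis import AgeStandardizer, basis_matrix

__all__ = [
    "RRMSpec",
    "VarianceParams",
    "DesignBundle",
    "RRMFit",
    "build_design",
    "reml_loglik",
    "reml_fit",
    "compare_models",
    "fit_reduced",
    "fit_pgs_adjusted",
    "fit_heterogeneous_residual",
]


@dataclass(frozen=True)
class RRMSpec:
    """Model specification: polynomial orders, covariates, residual structure."""

    k_f: int = 4
    k_g: int = 3
    k_i: int = 3
    covariates: tuple = ("sex", "source")
    pgs_interactions: bool = False
    residual_structure: str = "homogeneous"  # or "per-year"

    def __post_init__(self) -> None:
        if self.k_f < 1:
            raise ValueError("k_f must be >= 1")
        if self.k_g > self.k_f or self.k_i > self.k_f:
            raise ValueError("k_g and k_i must not exceed k_f")
        if self.k_g < 0 or self.k_i < 0:
            raise ValueError("negative polynomial order")
        if self.residual_structure not in ("homogeneous", "per-year"):
            raise ValueError("residual_structure must be 'homogeneous' or 'per-year'")

    @property
    def n_variance_params(self) -> int:
        nb = 17 if self.residual_structure == "per-year" else 1
        return self.k_g * (self.k_g + 1) // 2 + self.k_i * (self.k_i + 1) // 2 + nb


@dataclass
class VarianceParams:
    Kg: np.ndarray
    Ki: np.ndarray
    sigma2_e: np.ndarray  # length n_bins (1 for homogeneous)

    def __post_init__(self) -> None:
        self.Kg = np.atleast_2d(np.asarray(self.Kg, dtype=float)) if np.size(self.Kg) else np.zeros((0, 0))
        self.Ki = np.atleast_2d(np.asarray(self.Ki, dtype=float)) if np.size(self.Ki) else np.zeros((0, 0))
        self.sigma2_e = np.atleast_1d(np.asarray(self.sigma2_e, dtype=float))
        if np.any(self.sigma2_e <= 0):
            raise ValueError("residual variances must be positive")
        for K, name in ((self.Kg, "Kg"), (self.Ki, "Ki")):
            if K.size and not np.allclose(K, K.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")

    def pack(self) -> np.ndarray:
        return np.concatenate([vech(self.Kg) if self.Kg.size else np.empty(0),
                               vech(self.Ki) if self.Ki.size else np.empty(0),
                               self.sigma2_e])

    @staticmethod
    def unpack(vec, k_g: int, k_i: int, n_bins: int) -> "VarianceParams":
        vec = np.asarray(vec, dtype=float)
        ng = k_g * (k_g + 1) // 2
        ni = k_i * (k_i + 1) // 2
        Kg = unvech(vec[:ng], k_g) if k_g else np.zeros((0, 0))
        Ki = unvech(vec[ng : ng + ni], k_i) if k_i else np.zeros((0, 0))
        return VarianceParams(Kg=Kg, Ki=Ki, sigma2_e=vec[ng + ni :])

    def param_names(self) -> list:
        names = [f"Kg[{i + 1},{j + 1}]" for i, j in vech_indices(self.Kg.shape[0])]
        names += [f"Ki[{i + 1},{j + 1}]" for i, j in vech_indices(self.Ki.shape[0])]
        if len(self.sigma2_e) == 1:
            names.append("sigma2_e")
        else:
            names += [f"sigma2_e[bin{b + 1}]" for b in range(len(self.sigma2_e))]
        return names


@dataclass
class DesignBundle:
    """Response, fixed-effect design and per-record basis rows."""

    y: np.ndarray
    X: np.ndarray
    x_names: list
    ids: list  # unique individuals, sorted
    rec_indiv: np.ndarray  # record -> individual index
    Phi_g: np.ndarray  # n x k_g
    Phi_i: np.ndarray  # n x k_i
    bins: np.ndarray  # record -> residual bin index
    n_bins: int
    bin_labels: list
    spec: RRMSpec
    standardizer: AgeStandardizer

    @property
    def n_records(self) -> int:
        return self.y.size

    @property
    def n_individuals(self) -> int:
        return len(self.ids)


@dataclass
class RRMFit:
    """Converged (or diagnosed) REML fit."""

    b: np.ndarray
    b_se: np.ndarray
    x_names: list
    varparams: VarianceParams
    logl: float
    aic: float
    sampling_cov: np.ndarray
    param_names: list
    blup_g: np.ndarray  # N x k_g
    blup_i: np.ndarray  # N x k_i
    ids: list
    converged: bool
    n_iter: int
    grad_norm: float
    spec: RRMSpec
    standardizer: AgeStandardizer
    status: str = "converged"
    logl_trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# design construction


def _residual_bins(ages: np.ndarray, standardizer: AgeStandardizer):
    lo = int(np.floor(standardizer.min_age))
    hi = int(np.ceil(standardizer.max_age))
    idx = np.clip(np.floor(ages).astype(int), lo, hi - 1) - lo
    return idx, hi - lo


def build_design(
    pheno: pd.DataFrame,
    spec: RRMSpec | None = None,
    standardizer: AgeStandardizer | None = None,
    grm_ids=None,
    pgs=None,
) -> DesignBundle:
    """Assemble the response, fixed-effect matrix and basis rows for a fit.

    ``pheno`` is a cleaned long-format table (iid, sex, age, source, log_bmi)
    with all ages inside the standardizer window.  Records are sorted by
    (iid, age, source) so the design is invariant to input row order.  When
    ``grm_ids`` is given every phenotyped individual must appear in it.
    ``pgs`` (mapping iid -> score) adds a PGS main effect plus interactions
    with each non-constant fixed polynomial.
    """
    spec = spec or RRMSpec()
    standardizer = standardizer or AgeStandardizer()

    df = pheno.sort_values(["iid", "age", "source"], kind="stable").reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("empty phenotype table")
    ages = df["age"].to_numpy(dtype=float)
    if ages.min() < standardizer.min_age - 1e-9 or ages.max() > standardizer.max_age + 1e-9:
        raise ValueError("ages outside the standardizer window; filter phenotypes first")

    ids = sorted(df["iid"].unique().tolist())
    if grm_ids is not None:
        missing = set(ids) - set(grm_ids)
        if missing:
            raise ValueError(f"individuals absent from GRM ids: {sorted(missing)[:5]} ...")
    id_index = {iid: i for i, iid in enumerate(ids)}
    rec_indiv = df["iid"].map(id_index).to_numpy()

    m = standardizer.standardize(ages)
    Phi_f = basis_matrix(m, spec.k_f).values
    Phi_g = basis_matrix(m, spec.k_g).values if spec.k_g else np.zeros((len(df), 0))
    Phi_i = basis_matrix(m, spec.k_i).values if spec.k_i else np.zeros((len(df), 0))

    cols, names = [], []
    if "sex" in spec.covariates:
        sexes = [s for s in ("F", "M") if (df["sex"] == s).any()]
        for s in sexes:
            ind = (df["sex"] == s).to_numpy(dtype=float)[:, None]
            cols.append(ind * Phi_f)
            names += [f"sex={s}:phi{d}" for d in range(spec.k_f)]
    else:
        cols.append(Phi_f)
        names += [f"phi{d}" for d in range(spec.k_f)]
    if "source" in spec.covariates and "source" in df.columns:
        cols.append((df["source"] == "questionnaire").to_numpy(dtype=float)[:, None])
        names.append("source=questionnaire")
    if spec.pgs_interactions:
        if pgs is None:
            raise ValueError("spec requests PGS terms but no pgs mapping supplied")
        score = df["iid"].map(dict(pgs)).to_numpy(dtype=float)
        if np.any(~np.isfinite(score)):
            bad = df.loc[~np.isfinite(score), "iid"].unique()
            raise ValueError(f"missing PGS for individuals: {bad[:5]} ...")
        cols.append(score[:, None] * Phi_f)
        names += [f"pgs:phi{d}" for d in range(spec.k_f)]
    X = np.hstack(cols)

    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [
            names[j]
            for j in range(min(X.shape))
            if abs(R[j, j]) < 1e-8 * abs(R[0, 0])
        ] + [names[j] for j in range(min(X.shape), X.shape[1])]
        raise ValueError(f"rank-deficient fixed-effect design; offending columns: {bad}")

    bins = np.zeros(len(df), dtype=int)
    n_bins = 1
    labels = ["all"]
    if spec.residual_structure == "per-year":
        bins, n_raw = _residual_bins(ages, standardizer)
        present = np.nonzero(np.bincount(bins, minlength=n_raw))[0]
        if len(present) < n_raw:
            warnings.warn("empty residual bins merged with their lower neighbour")
        # map each raw bin to the nearest non-empty bin at or below (else above)
        remap = np.zeros(n_raw, dtype=int)
        labels = []
        for b in range(n_raw):
            below = present[present <= b]
            tgt = below[-1] if len(below) else present[0]
            remap[b] = np.searchsorted(present, tgt)
        bins = remap[bins]
        n_bins = len(present)
        lo = int(np.floor(standardizer.min_age))
        labels = [f"year {lo + int(b)}" for b in present]

    return DesignBundle(
        y=df["log_bmi"].to_numpy(dtype=float),
        X=X,
        x_names=names,
        ids=ids,
        rec_indiv=rec_indiv,
        Phi_g=Phi_g,
        Phi_i=Phi_i,
        bins=bins,
        n_bins=n_bins,
        bin_labels=labels,
        spec=spec,
        standardizer=standardizer,
    )


# ---------------------------------------------------------------------------
# mixed-model machinery

#: relative eigenvalue floor applied to GRMs before inversion.  A GRM built
#: with in-sample allele frequencies is exactly singular (column-centering
#: puts the ones vector in its null space), so the mixed-model equations use
#: a minimally lifted A; genetic effects in lifted directions are shrunk to
#: (near) zero, matching the singular prior.
GRM_MIN_REL_EIG = 1e-3


def regularize_grm_matrix(A: np.ndarray, min_rel_eig: float = GRM_MIN_REL_EIG) -> np.ndarray:
    """Floor the eigenvalues of a GRM at ``min_rel_eig`` times their mean.

    This is the effective relationship matrix used by the REML engine; it is
    exposed so that external likelihood computations can target the same
    model.
    """
    A = np.asarray(A, dtype=float)
    w, Q = np.linalg.eigh((A + A.T) / 2.0)
    floor = min_rel_eig * float(w.mean())
    if w.min() >= floor:
        return (A + A.T) / 2.0
    return (Q * np.clip(w, floor, None)) @ Q.T


class _MME:
    """Precomputed pieces of the mixed-model equations for one design/GRM.

    The individual-effect block of the equations is block-diagonal per
    individual, so it is absorbed (Schur complement) and only the reduced
    system over fixed effects and genetic coefficients, of dimension
    p + N*k_g, is ever factorized.
    """

    def __init__(self, design: DesignBundle, grm, k_g: int, k_i: int):
        self.design = design
        n = design.n_records
        N = design.n_individuals
        p = design.X.shape[1]
        self.n, self.N, self.p, self.kg, self.ki = n, N, p, k_g, k_i
        self.dim2 = p + N * k_g  # reduced (factorized) dimension

        if np.any(np.diff(design.rec_indiv) < 0):
            raise ValueError("records must be grouped by individual")
        self.starts = np.searchsorted(design.rec_indiv, np.arange(N))

        blocks = [sp.csr_matrix(design.X)]
        rows = np.arange(n)
        if k_g:
            cols = (design.rec_indiv[:, None] * k_g + np.arange(k_g)).ravel()
            blocks.append(
                sp.csr_matrix(
                    (design.Phi_g[:, :k_g].ravel(), (np.repeat(rows, k_g), cols)),
                    shape=(n, N * k_g),
                )
            )
        self.Wt = sp.hstack(blocks, format="csr")  # n x (p + N*kg)

        # per-record [x, phi_g] values and per-individual reduced-system
        # column indices, used for conditional-variance gathers
        self.A_rec = np.hstack([design.X, design.Phi_g])
        self.IDXa = np.empty((N, p + k_g), dtype=np.int64)
        self.IDXa[:, :p] = np.arange(p)
        if k_g:
            self.IDXa[:, p:] = p + np.arange(N)[:, None] * k_g + np.arange(k_g)

        if k_g:
            if grm is None:
                raise ValueError("a GRM is required when k_g > 0")
            A = np.asarray(grm.A, dtype=float)
            order = [grm.iids.index(i) for i in design.ids]
            A = regularize_grm_matrix(A[np.ix_(order, order)])
            w, Q = np.linalg.eigh(A)
            self.A = A
            self.logdetA = float(np.sum(np.log(w)))
            self.Ainv = (Q / w) @ Q.T
        else:
            self.A = self.Ainv = None
            self.logdetA = 0.0

    def reduceat(self, values: np.ndarray) -> np.ndarray:
        """Sum per-record values (first axis) within individuals."""
        return np.add.reduceat(values, self.starts, axis=0)


def _spd_inv_logdet(K: np.ndarray):
    """Inverse and log-determinant with a relative eigenvalue floor.

    Boundary iterates (eigenvalues of Kg/Ki approaching zero) would otherwise
    make the mixed-model equations numerically singular; flooring at 1e-7 of
    the leading eigenvalue keeps the penalty finite while pinning effects in
    the floored directions to (near) zero.
    """
    w, Q = np.linalg.eigh((K + K.T) / 2.0)
    if w.max() <= 0:
        raise np.linalg.LinAlgError("covariance matrix not positive definite")
    w = np.clip(w, 1e-7 * w.max(), None)
    return (Q / w) @ Q.T, float(np.sum(np.log(w)))


class _State:
    """Factorized MME at one parameter value (likelihood + solves).

    Only the reduced system over (fixed effects, genetic coefficients) is
    factorized; the per-individual blocks of the individual component are
    inverted batchwise and re-entered through Schur-complement identities.
    """

    def __init__(self, mme: _MME, vp: VarianceParams):
        d = mme.design
        n, N, p, kg, ki = mme.n, mme.N, mme.p, mme.kg, mme.ki
        self.mme, self.vp = mme, vp
        y = d.y
        sig = vp.sigma2_e[d.bins]
        self.rinv = 1.0 / sig
        logdetR = float(np.sum(np.log(sig)))

        Ct = (mme.Wt.T @ sp.diags(self.rinv) @ mme.Wt).toarray()
        rhs_a = mme.Wt.T @ (self.rinv * y)
        logdetG = 0.0
        self.Gg_inv = None  # kron(Ainv, Kginv), kept for score/AI identities
        self.Kiinv = None
        if kg:
            Kginv, ldg = _spd_inv_logdet(vp.Kg)
            self.Gg_inv = np.kron(mme.Ainv, Kginv)
            Ct[p:, p:] += self.Gg_inv
            logdetG += kg * mme.logdetA + N * ldg

        logdetD = 0.0
        rhs2 = rhs_a
        if ki:
            Kiinv, ldi = _spd_inv_logdet(vp.Ki)
            self.Kiinv = Kiinv
            logdetG += N * ldi
            Phi_i = d.Phi_i
            wPhi = self.rinv[:, None] * Phi_i
            D = mme.reduceat(wPhi[:, :, None] * Phi_i[:, None, :]) + Kiinv
            self.Dinv = np.linalg.inv(D)
            sgn, ld = np.linalg.slogdet(D)
            if np.any(sgn <= 0):
                raise np.linalg.LinAlgError("individual block not positive definite")
            logdetD = float(ld.sum())
            # A_i = per-individual cross-products between the i-block rows and
            # the reduced-system columns [x, g_i]
            self.Ai = mme.reduceat(wPhi[:, :, None] * mme.A_rec[:, None, :])
            self.rhs_i = mme.reduceat(wPhi * y[:, None])
            self.EA = np.matmul(self.Dinv, self.Ai)  # Dinv A_i
            S = np.matmul(np.transpose(self.Ai, (0, 2, 1)), self.EA)
            Ct[:p, :p] -= S[:, :p, :p].sum(axis=0)
            if kg:
                Sxg = S[:, :p, p:]  # N x p x kg
                strip = np.transpose(Sxg, (1, 0, 2)).reshape(p, N * kg)
                Ct[:p, p:] -= strip
                Ct[p:, :p] -= strip.T
                rows = p + (np.arange(N)[:, None, None] * kg + np.arange(kg)[None, :, None])
                cols = p + (np.arange(N)[:, None, None] * kg + np.arange(kg)[None, None, :])
                np.subtract.at(Ct, (rows, cols), S[:, p:, p:])
            red = np.matmul(
                np.transpose(self.Ai, (0, 2, 1)),
                np.matmul(self.Dinv, self.rhs_i[..., None]),
            )[..., 0]
            rhs2 = rhs_a.copy()
            rhs2[:p] -= red[:, :p].sum(axis=0)
            if kg:
                rhs2[p:] -= red[:, p:].reshape(N * kg)

        L, info = lapack.dpotrf(Ct, lower=1, overwrite_a=1)
        if info != 0:
            raise np.linalg.LinAlgError("MME coefficient matrix not positive definite")
        self.L = L
        logdetC = 2.0 * float(np.sum(np.log(np.diag(L)))) + logdetD

        theta2, _ = lapack.dpotrs(L, rhs2, lower=1)
        self.b = theta2[:p]
        self.ug = theta2[p:].reshape(N, kg) if kg else np.zeros((N, 0))
        th_ai = np.hstack([np.broadcast_to(self.b, (N, p)), self.ug])  # N x (p+kg)
        if ki:
            resid_i = self.rhs_i - np.matmul(self.Ai, th_ai[..., None])[..., 0]
            self.ui = np.matmul(self.Dinv, resid_i[..., None])[..., 0]
        else:
            self.ui = np.zeros((N, 0))

        yry = float(y @ (self.rinv * y))
        self.yPy = yry - float(self.b @ rhs_a[:p])
        if kg:
            self.yPy -= float(self.ug.ravel() @ rhs_a[p:])
        if ki:
            self.yPy -= float(np.sum(self.ui * self.rhs_i))
        self.logl = -0.5 * (
            (n - p) * np.log(2.0 * np.pi) + logdetR + logdetG + logdetC + self.yPy
        )

        idx = d.rec_indiv
        fitted = d.X @ self.b
        if kg:
            fitted = fitted + np.einsum("rk,rk->r", d.Phi_g, self.ug[idx])
        if ki:
            fitted = fitted + np.einsum("rk,rk->r", d.Phi_i, self.ui[idx])
        self.ehat = y - fitted
        self.Py = self.rinv * self.ehat
        self._Ctinv = None
        self._blocks = None

    @property
    def Ctinv(self) -> np.ndarray:
        """Inverse of the reduced coefficient matrix (= C^aa of the full MME)."""
        if self._Ctinv is None:
            Ci, _ = lapack.dpotri(self.L, lower=1)
            self._Ctinv = np.tril(Ci) + np.tril(Ci, -1).T
        return self._Ctinv

    def _indiv_blocks(self):
        """Per-individual pieces of the full-system inverse.

        Returns (P, M1, M2): P_i = C^aa over this individual's [x, g_i]
        columns; -M1_i = the [x, g_i] x i block; M2_i = C^ii diagonal block.
        """
        if self._blocks is None:
            Ci = self.Ctinv
            IDXa = self.mme.IDXa
            P = Ci[IDXa[:, :, None], IDXa[:, None, :]]
            if self.mme.ki:
                EAt = np.transpose(self.EA, (0, 2, 1))
                M1 = np.matmul(P, EAt)
                M2 = self.Dinv + np.matmul(self.EA, M1)
            else:
                M1 = M2 = None
            self._blocks = (P, M1, M2)
        return self._blocks

    def solve_reduced(self, B: np.ndarray) -> np.ndarray:
        out, _ = lapack.dpotrs(self.L, B, lower=1)
        return out

    def apply_P(self, F: np.ndarray) -> np.ndarray:
        """P F for record-space columns F (P the REML projection matrix)."""
        mme, d = self.mme, self.mme.design
        N, p, kg, ki = mme.N, mme.p, mme.kg, mme.ki
        RF = self.rinv[:, None] * F
        v_a = mme.Wt.T @ RF
        if ki:
            v_i = mme.reduceat(RF[:, None, :] * d.Phi_i[:, :, None])  # N,ki,k
            term = np.matmul(np.transpose(self.EA, (0, 2, 1)), v_i)  # N,p+kg,k
            v2 = v_a.copy()
            v2[:p] -= term[:, :p].sum(axis=0)
            if kg:
                v2[p:] -= term[:, p:].reshape(N * kg, -1)
        else:
            v2 = v_a
        z_a = self.solve_reduced(v2)
        idx = d.rec_indiv
        z_g = z_a[p:].reshape(N, kg, -1) if kg else None
        Wz = d.X @ z_a[:p]
        if kg:
            Wz = Wz + np.einsum("rk,rkj->rj", d.Phi_g, z_g[idx])
        if ki:
            z_ai = np.concatenate(
                [np.broadcast_to(z_a[:p], (N, p, F.shape[1])),
                 z_g if kg else np.zeros((N, 0, F.shape[1]))],
                axis=1,
            )
            z_i = np.matmul(self.Dinv, v_i - np.matmul(self.Ai, z_ai))
            Wz = Wz + np.einsum("rk,rkj->rj", d.Phi_i, z_i[idx])
        return RF - self.rinv[:, None] * Wz

    def record_quad(self) -> np.ndarray:
        """w_r' Cinv w_r for every record (conditional variance of fitted values)."""
        d = self.mme.design
        idx = d.rec_indiv
        P, M1, M2 = self._indiv_blocks()
        a = self.mme.A_rec
        q = np.einsum("ri,rij,rj->r", a, P[idx], a)
        if self.mme.ki:
            c = d.Phi_i
            q = q - 2.0 * np.einsum("ri,rij,rj->r", a, M1[idx], c)
            q = q + np.einsum("ri,rij,rj->r", c, M2[idx], c)
        return q


def _sym_bases(k: int):
    out = []
    for i, j in vech_indices(k):
        E = np.zeros((k, k))
        E[i, j] = 1.0
        E[j, i] = 1.0
        out.append(E)
    return out


def _score_and_ai(state: _State):
    """REML score vector and average-information matrix at the current point."""
    mme, d = state.mme, state.mme.design
    n, N, p, kg, ki = mme.n, mme.N, mme.p, mme.kg, mme.ki
    nb = d.n_bins
    Py = state.Py

    scores, Fcols = [], []

    if kg:
        # Zg' P Zg = G^-1 - G^-1 C^gg G^-1 (MME identity); C^gg of the full
        # system is the g-block of the reduced-system inverse
        Gg = state.Gg_inv
        Cgg = state.Ctinv[p:, p:]
        M = Gg - Gg @ Cgg @ Gg
        M4 = M.reshape(N, kg, N, kg)
        T = np.einsum("ij,jbia->ab", mme.A, M4)
        Sg = mme.reduceat(Py[:, None] * d.Phi_g)
        Q = Sg.T @ mme.A @ Sg
        ASg = mme.A @ Sg
        for E, (i, j) in zip(_sym_bases(kg), vech_indices(kg)):
            tr = T[i, j] + T[j, i] if i != j else T[i, i]
            qd = Q[i, j] + Q[j, i] if i != j else Q[i, i]
            scores.append(-0.5 * (tr - qd))
            t = ASg @ E
            Fcols.append(np.einsum("rk,rk->r", d.Phi_g, t[d.rec_indiv]))

    if ki:
        # diagonal blocks of Zi' P Zi = Kiinv - Kiinv C^ii_i Kiinv
        _, _, M2 = state._indiv_blocks()
        E2 = np.einsum("ab,ibc,cd->iad", state.Kiinv, M2, state.Kiinv)
        T = N * state.Kiinv - E2.sum(axis=0).T
        Si = mme.reduceat(Py[:, None] * d.Phi_i)
        Q = Si.T @ Si
        for E, (i, j) in zip(_sym_bases(ki), vech_indices(ki)):
            tr = T[i, j] + T[j, i] if i != j else T[i, i]
            qd = Q[i, j] + Q[j, i] if i != j else Q[i, i]
            scores.append(-0.5 * (tr - qd))
            t = Si @ E
            Fcols.append(np.einsum("rk,rk->r", d.Phi_i, t[d.rec_indiv]))

    q = state.record_quad()
    Pdiag = state.rinv - state.rinv**2 * q  # per-record diagonal of P
    for b in range(nb):
        mask = d.bins == b
        scores.append(-0.5 * (float(Pdiag[mask].sum()) - float((Py[mask] ** 2).sum())))
        Fcols.append(np.where(mask, Py, 0.0))

    F = np.column_stack(Fcols)
    PF = state.apply_P(F)
    AI = 0.5 * (F.T @ PF)
    AI = (AI + AI.T) / 2.0
    return np.asarray(scores), AI


def _em_update(state: _State) -> VarianceParams:
    """One EM-REML step (always stays inside the parameter space)."""
    mme, d = state.mme, state.mme.design
    N, p, kg, ki = mme.N, mme.p, mme.kg, mme.ki
    vp = state.vp

    Kg = vp.Kg
    if kg:
        Cgg = state.Ctinv[p:, p:].reshape(N, kg, N, kg)
        tr = np.einsum("ij,iajb->ab", mme.Ainv, Cgg)
        Kg = (state.ug.T @ mme.Ainv @ state.ug + tr) / N
        Kg = (Kg + Kg.T) / 2.0
    Ki = vp.Ki
    if ki:
        _, _, M2 = state._indiv_blocks()
        Ki = (state.ui.T @ state.ui + M2.sum(axis=0)) / N
        Ki = (Ki + Ki.T) / 2.0

    q = state.record_quad()
    sig = np.empty(d.n_bins)
    for b in range(d.n_bins):
        mask = d.bins == b
        sig[b] = float(np.sum(state.ehat[mask] ** 2 + q[mask])) / float(mask.sum())
    return VarianceParams(Kg=Kg, Ki=Ki, sigma2_e=sig)


def _tril_pairs(k: int):
    return [(i, j) for i in range(k) for j in range(i + 1)]


def _chol_factor(K: np.ndarray) -> np.ndarray:
    """Cholesky factor of a (possibly barely non-PD) covariance matrix."""
    k = K.shape[0]
    if k == 0:
        return np.zeros((0, 0))
    scale = max(float(np.trace(K)) / k, 1e-30)
    try:
        return np.linalg.cholesky(K + 1e-10 * scale * np.eye(k))
    except np.linalg.LinAlgError:
        w, Q = np.linalg.eigh((K + K.T) / 2.0)
        w = np.clip(w, 1e-10 * scale, None)
        return np.linalg.cholesky((Q * w) @ Q.T)


def _vp_to_chol(vp: VarianceParams) -> np.ndarray:
    """Unconstrained coordinates: tril(chol Kg), tril(chol Ki), log sigma2."""
    parts = []
    for K in (vp.Kg, vp.Ki):
        L = _chol_factor(K)
        parts.append(np.array([L[i, j] for i, j in _tril_pairs(K.shape[0])]))
    parts.append(np.log(vp.sigma2_e))
    return np.concatenate(parts)


def _chol_to_vp(c: np.ndarray, kg: int, ki: int, n_bins: int) -> VarianceParams:
    ng = kg * (kg + 1) // 2
    ni = ki * (ki + 1) // 2
    mats = []
    off = 0
    for k, nn in ((kg, ng), (ki, ni)):
        L = np.zeros((k, k))
        for val, (i, j) in zip(c[off : off + nn], _tril_pairs(k)):
            L[i, j] = val
        mats.append(L @ L.T)
        off += nn
    return VarianceParams(Kg=mats[0], Ki=mats[1], sigma2_e=np.exp(c[off:]))


def _chol_jacobian(c: np.ndarray, kg: int, ki: int, n_bins: int) -> np.ndarray:
    """d(theta)/d(c): variance-scale parameters vs Cholesky/log coordinates."""
    ng = kg * (kg + 1) // 2
    ni = ki * (ki + 1) // 2
    ntot = ng + ni + n_bins
    J = np.zeros((ntot, ntot))
    off = 0
    for k, nn in ((kg, ng), (ki, ni)):
        L = np.zeros((k, k))
        for val, (i, j) in zip(c[off : off + nn], _tril_pairs(k)):
            L[i, j] = val
        vidx = vech_indices(k)
        for col, (a, b) in enumerate(_tril_pairs(k)):
            # dK = E_ab L' + L E_ab'
            for row, (i, j) in enumerate(vidx):
                val = (L[j, b] if i == a else 0.0) + (L[i, b] if j == a else 0.0)
                J[off + row, off + col] = val
        off += nn
    J[off:, off:] = np.diag(np.exp(c[off:]))
    return J


def _effective_orders(vp: VarianceParams):
    kg = vp.Kg.shape[0] if vp.Kg.size and np.any(vp.Kg) else 0
    ki = vp.Ki.shape[0] if vp.Ki.size and np.any(vp.Ki) else 0
    return kg, ki


def reml_loglik(varparams: VarianceParams, design: DesignBundle, grm=None) -> float:
    """Restricted log-likelihood at fixed variance parameters.

    All-zero Kg or Ki matrices are treated as absent random components (the
    degenerate limit), so e.g. Kg = Ki = 0 gives the OLS residual REML
    likelihood.
    """
    kg, ki = _effective_orders(varparams)
    if kg not in (0, design.spec.k_g) or ki not in (0, design.spec.k_i):
        raise ValueError("variance parameter orders do not match the design")
    mme = _MME(design, grm, kg, ki)
    vp = VarianceParams(
        Kg=varparams.Kg if kg else np.zeros((0, 0)),
        Ki=varparams.Ki if ki else np.zeros((0, 0)),
        sigma2_e=varparams.sigma2_e,
    )
    return _State(mme, vp).logl


def reml_fit(
    design: DesignBundle,
    grm=None,
    init: VarianceParams | None = None,
    max_iter: int = 200,
    tol_logl: float = 1e-6,
    tol_param: float = 1e-4,
    n_em: int = 5,
    verbose: bool = False,
) -> RRMFit:
    """Fit the random regression model by EM-warm-started AI-REML.

    Convergence requires both |change in logL| < ``tol_logl`` and a maximum
    relative parameter change below ``tol_param``.  Non-convergence returns a
    flagged fit rather than raising.
    """
    spec = design.spec
    kg, ki = spec.k_g, spec.k_i
    if design.n_individuals < 2:
        raise ValueError("need at least two individuals")
    mme = _MME(design, grm, kg, ki)

    if init is None:
        vy = float(np.var(design.y))
        # asymmetric start: most non-residual variance on the individual
        # component, a small genetic seed.  A symmetric start lets Kg absorb
        # individual-level covariance early and can strand the fit in an
        # inferior local optimum when genetic identification is weak.
        init = VarianceParams(
            Kg=0.03 * vy * np.eye(kg) if kg else np.zeros((0, 0)),
            Ki=0.4 * vy * np.eye(ki) if ki else np.zeros((0, 0)),
            sigma2_e=np.full(design.n_bins, 0.5 * vy),
        )
    vp = init
    state = _State(mme, vp)
    status = "running"
    grad_norm = np.inf
    it = 0
    n_flat = 0
    trace = [float(state.logl)]
    for it in range(1, max_iter + 1):
        if it <= n_em:
            new_vp = _em_update(state)
            new_state = _State(mme, new_vp)
        else:
            # Newton step in Cholesky/log coordinates: PSD by construction,
            # so step-halving only guards the likelihood ascent
            score, AI = _score_and_ai(state)
            grad_norm = float(np.max(np.abs(score)))
            c0 = _vp_to_chol(vp)
            J = _chol_jacobian(c0, kg, ki, design.n_bins)
            score_c = J.T @ score
            AI_c = J.T @ AI @ J
            ridge = 1e-10 * max(np.trace(AI_c) / max(AI_c.shape[0], 1), 1e-30)
            try:
                delta = np.linalg.solve(AI_c + ridge * np.eye(AI_c.shape[0]), score_c)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(AI_c, score_c, rcond=None)[0]
            step = 1.0
            new_state = None
            for _ in range(30):
                cand = _chol_to_vp(c0 + step * delta, kg, ki, design.n_bins)
                try:
                    trial = _State(mme, cand)
                except np.linalg.LinAlgError:
                    step /= 2.0
                    continue
                if trial.logl >= state.logl - 1e-10:
                    new_state, new_vp = trial, cand
                    break
                step /= 2.0
            if new_state is None:  # Newton step irrecoverable; fall back to EM
                new_vp = _em_update(state)
                new_state = _State(mme, new_vp)
                if new_state.logl < state.logl - 1e-8:
                    # neither Newton nor EM improves: numerically at the optimum
                    status = "converged"
                    break

        dl = new_state.logl - state.logl
        old = vp.pack()
        scale = float(np.max(np.abs(old))) + 1e-30  # floor tiny components
        rel = np.max(np.abs(new_vp.pack() - old) / (np.abs(old) + 1e-3 * scale))
        if verbose:
            print(f"iter {it}: logL = {new_state.logl:.6f} (dl = {dl:.2e}, drel = {rel:.2e})")
        vp, state = new_vp, new_state
        trace.append(float(state.logl))
        if it > n_em and abs(dl) < tol_logl:
            n_flat += 1
            # primary criterion: flat likelihood AND settled parameters;
            # three consecutive flat-likelihood steps also count (parameters
            # can drift along a likelihood-flat ridge near the PSD boundary)
            if rel < tol_param or n_flat >= 3:
                status = "converged"
                break
        else:
            n_flat = 0
        # stagnation guard: a PSD-boundary ridge can yield tiny but
        # above-tolerance gains for many iterations; stop once ten
        # iterations together improve logL by less than 1e-4
        if it > n_em + 10 and trace[-1] - trace[-11] < 1e-4:
            status = "converged"
            break
    else:
        status = "max_iter"
        warnings.warn("REML did not converge within max_iter; returning diagnostics")

    score, AI = _score_and_ai(state)
    grad_norm = float(np.max(np.abs(score)))
    try:
        sampling_cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        sampling_cov = np.linalg.pinv(AI)
        status += "+singular_ai"
    sampling_cov = (sampling_cov + sampling_cov.T) / 2.0

    p = mme.p
    b = state.b
    b_se = np.sqrt(np.clip(np.diag(state.Ctinv)[:p], 0.0, None))
    blup_g = state.ug
    blup_i = state.ui

    n_vpar = len(vp.pack())
    return RRMFit(
        b=b,
        b_se=b_se,
        x_names=design.x_names,
        varparams=vp,
        logl=float(state.logl),
        aic=float(-2.0 * state.logl + 2.0 * n_vpar),
        sampling_cov=sampling_cov,
        param_names=vp.param_names(),
        blup_g=blup_g,
        blup_i=blup_i,
        ids=design.ids,
        converged=status.startswith("converged"),
        n_iter=it,
        grad_norm=grad_norm,
        spec=spec,
        standardizer=design.standardizer,
        status=status,
        logl_trace=trace,
    )


def fit_reduced(design: DesignBundle, **kwargs) -> RRMFit:
    """Fit the reduced model with individual-specific random effects only.

    ``design`` must have been built with a spec where ``k_g = 0``; no GRM is
    needed.  The individual BLUPs are retained for derived-phenotype GWAS.
    """
    if design.spec.k_g != 0:
        raise ValueError("build the design with k_g = 0 for the reduced model")
    return reml_fit(design, grm=None, **kwargs)


def fit_pgs_adjusted(design: DesignBundle, grm, **kwargs) -> RRMFit:
    """Fit the model whose fixed effects include PGS and PGS-by-age terms."""
    if not design.spec.pgs_interactions:
        raise ValueError("design lacks PGS fixed-effect columns")
    return reml_fit(design, grm=grm, **kwargs)


def fit_heterogeneous_residual(design: DesignBundle, grm, **kwargs) -> RRMFit:
    """Fit with one residual variance per yearly age bin."""
    if design.spec.residual_structure != "per-year":
        raise ValueError("build the design with residual_structure='per-year'")
    return reml_fit(design, grm=grm, **kwargs)


def compare_models(fit_a: RRMFit, fit_b: RRMFit) -> dict:
    """AIC difference and likelihood-ratio test between two nested fits.

    The fits must share identical fixed effects (REML likelihoods are not
    comparable otherwise).  The LRT df is the difference in variance-parameter
    count; the naive chi-square p-value is reported with a boundary caveat
    flag because variance parameters on the boundary make it conservative.
    """
    if fit_a.x_names != fit_b.x_names:
        raise ValueError("fits have different fixed effects; REML LRT undefined")
    full, red = (fit_a, fit_b) if len(fit_a.param_names) >= len(fit_b.param_names) else (fit_b, fit_a)
    nested = (
        full.spec.k_g >= red.spec.k_g
        and full.spec.k_i >= red.spec.k_i
        and len(full.varparams.sigma2_e) >= len(red.varparams.sigma2_e)
    )
    if not nested:
        raise ValueError("specs are not nested; LRT undefined")
    df = len(full.param_names) - len(red.param_names)
    lrt = 2.0 * (full.logl - red.logl)
    p = 1.0 if df == 0 else float(_chi2.sf(max(lrt, 0.0), df))
    return {
        "delta_aic": fit_a.aic - fit_b.aic,
        "lrt": lrt,
        "df": df,
        "p": p,
        "boundary_caveat": True,
    }
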