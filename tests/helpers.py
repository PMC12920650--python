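"""Independent oracles and shared builders for the test suite.

These deliberately avoid the package's mixed-model-equation code paths: the
dense oracle builds V explicitly and uses the projection form of the
restricted likelihood; the two-component oracle maximizes it numerically.
"""

import numpy as np
from scipy.optimize import minimize

from longrrm.grm import GRM, GenotypePanel, build_grm
from longrrm.reml import regularize_grm_matrix
from longrrm.simulate import SimConfig, simulate_cohort, simulate_genotypes


def dense_reml_loglik(vp, design, A):
    """Projection-form restricted likelihood from an explicit dense V."""
    n, N = design.n_records, design.n_individuals
    kg = vp.Kg.shape[0] if vp.Kg.size and np.any(vp.Kg) else 0
    ki = vp.Ki.shape[0] if vp.Ki.size and np.any(vp.Ki) else 0
    V = np.diag(vp.sigma2_e[design.bins]).astype(float)
    if kg:
        Zg = np.zeros((n, N * kg))
        for r in range(n):
            i = design.rec_indiv[r]
            Zg[r, i * kg : (i + 1) * kg] = design.Phi_g[r, :kg]
        V += Zg @ np.kron(A, vp.Kg) @ Zg.T
    if ki:
        Zi = np.zeros((n, N * ki))
        for r in range(n):
            i = design.rec_indiv[r]
            Zi[r, i * ki : (i + 1) * ki] = design.Phi_i[r, :ki]
        V += Zi @ np.kron(np.eye(N), vp.Ki) @ Zi.T
    X, y = design.X, design.y
    p = X.shape[1]
    Vinv = np.linalg.inv(V)
    XVX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XVX) @ X.T @ Vinv
    return -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XVX)[1]
        + float(y @ P @ y)
    )


def greml_two_component_oracle(y, X, A):
    """Direct 2-parameter REML for V = s_a * A + s_e * I.

    Works in the eigenbasis of A (computed once) so each projection-form
    likelihood evaluation is diagonal; maximized numerically.
    """
    n, p = X.shape
    w, Q = np.linalg.eigh((A + A.T) / 2.0)
    yt = Q.T @ y
    Xt = Q.T @ X

    def negll(logpar):
        sa, se = np.exp(logpar)
        d = sa * w + se
        if d.min() <= 0:
            return 1e12
        Xd = Xt / d[:, None]
        XVX = Xt.T @ Xd
        sX, ldX = np.linalg.slogdet(XVX)
        if sX <= 0:
            return 1e12
        beta = np.linalg.solve(XVX, Xd.T @ yt)
        yPy = float(yt @ (yt / d)) - float((Xd.T @ yt) @ beta)
        return 0.5 * (
            (n - p) * np.log(2 * np.pi) + float(np.sum(np.log(d))) + ldX + yPy
        )

    vy = np.var(y)
    best = None
    for f in (0.1, 0.3, 0.6):
        res = minimize(
            negll,
            np.log([f * vy, (1 - f) * vy]),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 6000},
        )
        if best is None or res.fun < best.fun:
            best = res
    sa, se = np.exp(best.x)
    return sa, se, -best.fun


def polymorphic_genotypes(n, m, seed, maf_range=(0.1, 0.5)):
    G, _ = simulate_genotypes(n, m, maf_range=maf_range, seed=seed)
    keep = (G.mean(axis=0) > 0.05) & (G.mean(axis=0) < 1.95)
    return G[:, keep]


def make_cohort(n=60, m=300, seed=0, **cfg_kw):
    """Simulated cohort + GRM + raw genotypes for REML-level tests."""
    G = polymorphic_genotypes(n, m, seed)
    cfg = SimConfig(n_individuals=n, n_snps=G.shape[1], seed=seed, **cfg_kw)
    pheno, truth = simulate_cohort(G, cfg)
    panel = GenotypePanel(iids=sorted(pheno["iid"].unique()), snps=None, genotypes=G)
    grm = build_grm(panel)
    return pheno, truth, grm, G


def effective_A(grm: GRM, ids):
    """The regularized relationship matrix the REML engine actually uses."""
    order = [grm.iids.index(i) for i in ids]
    return regularize_grm_matrix(np.asarray(grm.A, float)[np.ix_(order, order)])
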