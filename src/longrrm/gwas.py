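"""GWAS on BLUP-derived trajectory phenotypes.

Phenotypes are the reduced model's per-individual polynomial coefficients
(intercept, linear slope, quadratic) plus their PC1/PC2 linear combinations.
Association is plain per-SNP ordinary least squares with the top GRM PCs as
covariates; the GRM enters only through those PCs.  Residualizing phenotype
and genotypes on the covariates (Frisch-Waugh-Lovell) makes the per-SNP scan
a single vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from longrrm.grm import GenotypePanel
from longrrm.reml import RRMFit

__all__ = [
    "DerivedPhenotypes",
    "derive_phenotypes",
    "gwas",
    "lambda_gc",
    "clump",
    "write_sumstats",
    "read_sumstats",
]

GENOME_WIDE_P = 5e-8


@dataclass
class DerivedPhenotypes:
    table: pd.DataFrame  # iid, intercept, slope, quadratic, pc1, pc2

    @property
    def names(self):
        return [c for c in self.table.columns if c != "iid"]


def derive_phenotypes(reduced_fit: RRMFit, E: np.ndarray) -> DerivedPhenotypes:
    """Trajectory phenotypes from reduced-model individual BLUPs.

    Uses the first three BLUP columns (intercept, linear, quadratic) and the
    first two columns of ``E`` as PC weights.  Requires k_i >= 3.
    """
    if reduced_fit.blup_i.shape[1] < 3:
        raise ValueError("reduced fit must have k_i >= 3 for trajectory phenotypes")
    B = reduced_fit.blup_i[:, :3]
    tbl = pd.DataFrame(
        {
            "iid": reduced_fit.ids,
            "intercept": B[:, 0],
            "slope": B[:, 1],
            "quadratic": B[:, 2],
            "pc1": B @ E[:, 0],
            "pc2": B @ E[:, 1],
        }
    )
    return DerivedPhenotypes(table=tbl)


def gwas(genotypes, phenotype, covariates=None, panel: GenotypePanel | None = None) -> pd.DataFrame:
    """Per-SNP OLS of a phenotype on dosage plus covariates.

    ``genotypes`` is N x M (dosages or hard calls; the caller QCs them);
    ``covariates`` is N x c and must not contain a constant column (an
    intercept is always included and redundant columns are an error, not
    silently dropped).  Returns a summary-statistic table; SNP metadata is
    taken from ``panel`` when given.
    """
    if panel is not None and genotypes is None:
        genotypes = panel.genotypes
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, m = G.shape
    if y.size != n:
        raise ValueError("phenotype length does not match genotypes")
    if np.std(y) == 0:
        raise ValueError("constant phenotype")
    Z = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        Z = np.hstack([Z, C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear covariates (constant columns are rejected, not dropped)")

    # Frisch-Waugh-Lovell: residualize phenotype and dosages on covariates
    Q, _ = np.linalg.qr(Z)
    yr = y - Q @ (Q.T @ y)
    Gr = G - Q @ (Q.T @ G)

    gg = np.einsum("ij,ij->j", Gr, Gr)
    ok = gg > 1e-12
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    beta[ok] = (Gr[:, ok].T @ yr) / gg[ok]
    df = n - Z.shape[1] - 1
    rss = float(yr @ yr) - beta[ok] ** 2 * gg[ok]
    se[ok] = np.sqrt(rss / df / gg[ok])
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    freq = np.nanmean(G, axis=0) / 2.0
    out = pd.DataFrame(
        {
            "SNP": panel.snps["snp"] if panel is not None else [f"snp{j + 1}" for j in range(m)],
            "CHR": panel.snps["chrom"] if panel is not None else 1,
            "BP": panel.snps["pos"] if panel is not None else (np.arange(m) + 1) * 10_000,
            "A1": panel.snps["a1"] if panel is not None else "A",
            "A2": panel.snps["a2"] if panel is not None else "G",
            "FREQ": freq,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n,
        }
    )
    out["genome_wide"] = out["P"] < GENOME_WIDE_P
    return out


def lambda_gc(pvalues) -> float:
    """Genomic-control inflation: median implied 1-df chi-square over 0.45494."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values for lambda GC")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def clump(results: pd.DataFrame, window_bp: int = 1_000_000, p_max: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Lead SNPs by lowest p within a fixed window, per chromosome."""
    sig = results[results["P"] < p_max].sort_values("P")
    leads = []
    taken: list[tuple] = []
    for _, row in sig.iterrows():
        if any(c == row["CHR"] and abs(b - row["BP"]) <= window_bp for c, b in taken):
            continue
        leads.append(row)
        taken.append((row["CHR"], row["BP"]))
    return pd.DataFrame(leads).reset_index(drop=True)


_SUMSTAT_COLS = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "P", "N"]


def write_sumstats(results: pd.DataFrame, path: str) -> None:
    # default float formatting is shortest-round-trip repr: read() is bit-exact
    results[_SUMSTAT_COLS].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
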