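"""SNP QC, genomic relationship matrices, relatedness pruning and GRM PCs.

The GRM follows the standard allele-frequency-standardized cross-product

    A_jk = (1/M) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with in-sample frequencies p_i, applied to diagonal and off-diagonal entries
alike.  Missing genotypes are mean-imputed per SNP before standardization.
Binary I/O is compatible with the GCTA triplet (grm.bin / grm.N.bin / grm.id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from longrrm import _plink

__all__ = [
    "GenotypePanel",
    "GRM",
    "snp_qc",
    "build_grm",
    "prune_related",
    "grm_pca",
    "write_grm",
    "read_grm",
    "read_plink",
    "write_plink",
]


@dataclass
class GenotypePanel:
    """Hard-call (or dosage) genotypes with per-SNP metadata."""

    iids: list
    snps: pd.DataFrame  # chrom, snp, cm, pos, a1, a2
    genotypes: np.ndarray  # N x M, values in [0, 2] or NaN
    info: np.ndarray | None = None  # imputation INFO scores, optional

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """In-sample A1 allele frequencies, ignoring missing calls."""
        return np.nanmean(self.genotypes, axis=0) / 2.0

    def missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.genotypes), axis=0)


@dataclass
class GRM:
    iids: list
    A: np.ndarray
    n_snps: int
    pair_counts: np.ndarray = field(default=None)  # per-pair non-missing SNP counts

    def __post_init__(self) -> None:
        if self.pair_counts is None:
            n = len(self.iids)
            self.pair_counts = np.full((n, n), float(self.n_snps), dtype=np.float32)


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value for biallelic hard calls.

    Sums probabilities of heterozygote counts no more likely than the
    observed one, conditional on allele counts (Wigginton-style recursion).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # probabilities over possible het counts with same parity as rare
    probs = {}
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    # downward recursion
    het = mid
    while het >= 2:
        nh1 = (rare - het) // 2
        nh2 = n - het - nh1
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (nh1 + 1) * (nh2 + 1))
        het -= 2
    het = mid
    while het <= rare - 2:
        nh1 = (rare - het) // 2
        nh2 = n - het - nh1
        probs[het + 2] = probs[het] * 4.0 * nh1 * nh2 / ((het + 2.0) * (het + 1.0))
        het += 2
    total = sum(probs.values())
    p_obs = probs.get(n_het, 0.0)
    p = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def snp_qc(
    panel: GenotypePanel,
    miss_max: float = 0.05,
    hwe_p_min: float = 1e-6,
    maf_min: float = 0.01,
    info_min: float = 0.8,
):
    """Filter SNPs by missingness, HWE, INFO and MAF (applied in that order).

    The INFO filter is skipped when the panel carries no scores (hard-call
    data from arrays or simulation has none).  Returns ``(panel, counts)``
    with removal counts per filter in application order.
    """
    if panel.n_snps == 0:
        raise ValueError("empty genotype panel")
    G = panel.genotypes
    keep = np.ones(panel.n_snps, dtype=bool)
    counts = {}

    miss = panel.missingness()
    drop = keep & (miss > miss_max)
    counts["missingness"] = int(drop.sum())
    keep &= ~drop

    hwe_p = np.ones(panel.n_snps)
    for j in np.nonzero(keep)[0]:
        g = G[:, j]
        g = g[np.isfinite(g)]
        n_hom2 = int(np.sum(g == 0))
        n_het = int(np.sum(g == 1))
        n_hom1 = int(np.sum(g == 2))
        hwe_p[j] = hwe_exact_p(n_het, n_hom1, n_hom2)
    drop = keep & (hwe_p < hwe_p_min)
    counts["hwe"] = int(drop.sum())
    keep &= ~drop

    if panel.info is not None:
        drop = keep & (panel.info < info_min)
        counts["info"] = int(drop.sum())
        keep &= ~drop
    else:
        counts["info"] = 0

    freq = panel.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    drop = keep & (maf < maf_min)
    counts["maf"] = int(drop.sum())
    keep &= ~drop

    if not keep.any():
        raise ValueError("all SNPs removed by QC")
    out = GenotypePanel(
        iids=list(panel.iids),
        snps=panel.snps[keep].reset_index(drop=True),
        genotypes=G[:, keep],
        info=None if panel.info is None else panel.info[keep],
    )
    return out, counts


def build_grm(panel: GenotypePanel) -> GRM:
    """Construct the GRM from a QC'd panel (mean-imputing missing calls)."""
    G = panel.genotypes.astype(float)
    p = panel.allele_frequencies()
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic SNP present; run snp_qc first")
    miss = np.isnan(G)
    obs = (~miss).astype(np.float32)
    if miss.any():
        G = np.where(miss, 2.0 * p, G)
    Z = (G - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m = panel.n_snps
    A = (Z @ Z.T) / m
    A = (A + A.T) / 2.0
    counts = obs @ obs.T
    return GRM(iids=list(panel.iids), A=A, n_snps=m, pair_counts=counts)


def prune_related(grm: GRM, cutoff: float = 0.05, seed: int = 0) -> list:
    """Greedy pruning so that no kept pair has relatedness above ``cutoff``.

    Repeatedly removes the individual involved in the most above-cutoff pairs,
    breaking ties with a seeded random draw.  Returns the kept iids.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rng = np.random.default_rng(seed)
    n = len(grm.iids)
    adj = np.abs(grm.A) > cutoff
    np.fill_diagonal(adj, False)
    active = np.ones(n, dtype=bool)
    while True:
        deg = (adj & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        dmax = deg.max()
        if dmax == 0:
            break
        cand = np.nonzero(deg == dmax)[0]
        drop = cand[rng.integers(len(cand))] if len(cand) > 1 else cand[0]
        active[drop] = False
    return [grm.iids[i] for i in np.nonzero(active)[0]]


def grm_pca(grm: GRM, n_components: int = 10) -> np.ndarray:
    """Leading principal component scores of the GRM.

    Eigenvectors of A scaled by the square root of their eigenvalue, in
    descending eigenvalue order, signs fixed so the largest-magnitude loading
    of each PC is positive.
    """
    n = len(grm.iids)
    if n_components > n:
        raise ValueError("n_components exceeds the number of individuals")
    w, V = np.linalg.eigh((grm.A + grm.A.T) / 2.0)
    order = np.argsort(w)[::-1][:n_components]
    w, V = w[order], V[:, order]
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    return V * np.sqrt(np.clip(w, 0.0, None))


def write_grm(grm: GRM, prefix: str) -> None:
    """Write the GCTA binary triplet (lower triangle row-wise, float32)."""
    n = len(grm.iids)
    tri = np.concatenate([grm.A[i, : i + 1] for i in range(n)]).astype("<f4")
    tri.tofile(f"{prefix}.grm.bin")
    cnt = np.concatenate([grm.pair_counts[i, : i + 1] for i in range(n)]).astype("<f4")
    cnt.tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in grm.iids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm(prefix: str) -> GRM:
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)
    iids = ids[1].astype(str).tolist()
    n = len(iids)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    cnt = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError("grm.bin size does not match grm.id")
    A = np.zeros((n, n), dtype=np.float32)
    counts = np.zeros((n, n), dtype=np.float32)
    k = 0
    for i in range(n):
        A[i, : i + 1] = tri[k : k + i + 1]
        counts[i, : i + 1] = cnt[k : k + i + 1]
        k += i + 1
    A = A + np.tril(A, -1).T
    counts = counts + np.tril(counts, -1).T
    return GRM(iids=iids, A=A, n_snps=int(round(float(counts[0, 0]))), pair_counts=counts)


def read_plink(prefix: str) -> GenotypePanel:
    G, iids, bim = _plink.read_bed(prefix)
    return GenotypePanel(iids=iids, snps=bim, genotypes=G)


def write_plink(panel: GenotypePanel, prefix: str) -> None:
    _plink.write_bed(prefix, panel.genotypes, panel.iids, panel.snps)
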