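"""Synthetic genotypes and longitudinal log-BMI cohorts with known truth.

The generative model mirrors the analysis model: each individual's trait at
standardized age m is

    y = phi_f(m)' beta_sex + offset * 1[questionnaire]
        + phi_g(m)' alpha_g + phi_i(m)' alpha_i + e

with genetic coefficients alpha_g whose covariance across individuals is
A (x) Kg for the realized genomic relationship matrix A, individual
coefficients alpha_i ~ iid MVN(0, Ki) and residuals e ~ N(0, sigma2_e).

By default alpha_g is built SNP-wise: alpha_g = W U with W the
column-standardized genotype matrix and U per-SNP effects drawn iid
MVN(0, Kg / M), which gives var(alpha_g) = A (x) Kg exactly for the realized
A = W W' / M without an N x N Cholesky.  A direct Cholesky route over
A (x) Kg is available for small N ("cholesky" method) and is tested for
distributional equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from longrrm.basis import AgeStandardizer, basis_matrix
from longrrm._linalg import is_psd

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_kg",
    "default_ki",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_adult_pgs_weights",
]


def default_kg() -> np.ndarray:
    """3x3 genetic coefficient covariance assembled from the default
    component variances (0.0073, 0.0017, 0.0004) and correlations
    (0.682, -0.678, -0.473)."""
    d = np.array([0.0073, 0.0017, 0.0004])
    s = np.sqrt(d)
    K = np.diag(d)
    K[0, 1] = K[1, 0] = 0.682 * s[0] * s[1]
    K[0, 2] = K[2, 0] = -0.678 * s[0] * s[2]
    K[1, 2] = K[2, 1] = -0.473 * s[1] * s[2]
    return K


def default_ki() -> np.ndarray:
    return np.diag([0.0144, 0.0054, 0.0037])


# wave ages mimic a birth cohort with dense early and school-age follow-up
# but sparse coverage at 3-6 years
DEFAULT_WAVE_AGES = (
    1.0, 1.5, 2.0, 3.5, 5.0, 6.5, 7.5, 8.5, 9.5, 10.5,
    11.5, 12.5, 13.5, 14.5, 15.5, 16.5, 17.75,
)


@dataclass
class SimConfig:
    n_individuals: int = 500
    n_snps: int = 2000
    maf_range: tuple = (0.05, 0.5)
    Kg: np.ndarray = field(default_factory=default_kg)
    Ki: np.ndarray = field(default_factory=default_ki)
    sigma2_e: float = 0.004
    # per-sex fixed cubic curves on the scaled Legendre basis (k_f = 4)
    fixed_curve: dict = field(
        default_factory=lambda: {
            "F": np.array([4.00, 0.20, 0.10, 0.02]),
            "M": np.array([3.98, 0.22, 0.09, 0.02]),
        }
    )
    source_offset: float = -0.01  # questionnaire relative to clinic
    questionnaire_prob: float = 0.3
    mean_measurements: float = 10.5
    sd_measurements: float = 3.8
    min_measurements: int = 4
    wave_ages: tuple = DEFAULT_WAVE_AGES
    wave_jitter_sd: float = 0.1
    dropout: float = 0.0  # 0 = missing completely at random
    seed: int = 0
    standardizer: AgeStandardizer = field(default_factory=AgeStandardizer)

    @property
    def k_g(self) -> int:
        return self.Kg.shape[0]

    @property
    def k_i(self) -> int:
        return self.Ki.shape[0]

    def validate(self) -> None:
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")
        if not is_psd(self.Kg, 1e-10) or not is_psd(self.Ki, 1e-10):
            raise ValueError("Kg and Ki must be symmetric PSD")
        if len(self.wave_ages) < self.min_measurements:
            raise ValueError("schedule cannot satisfy the minimum measurement count")


@dataclass
class SimTruth:
    """Ground-truth quantities recorded by the simulator for recovery tests."""

    alpha_g: np.ndarray  # N x k_g true genetic coefficients
    alpha_i: np.ndarray  # N x k_i true individual coefficients
    snp_effects: np.ndarray | None  # M x k_g per-SNP effect vectors (SNP-wise route)
    grm: np.ndarray  # realized GRM A = W W' / M
    allele_freq: np.ndarray
    config: SimConfig


def simulate_genotypes(n: int, m_snps: int, maf_range=(0.05, 0.5), seed: int = 0):
    """Draw independent hard-call genotypes; SNP i is binomial(2, p_i) with
    p_i ~ Uniform(maf_range).  Returns (genotypes, drawn frequencies)."""
    if n < 2 or m_snps < 1:
        raise ValueError("need n >= 2 individuals and at least one SNP")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=m_snps)
    G = rng.binomial(2, p, size=(n, m_snps)).astype(float)
    return G, p


def _standardize_columns(G: np.ndarray) -> np.ndarray:
    p = G.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    sd[sd == 0] = 1.0
    return (G - 2.0 * p) / sd


def simulate_cohort(genotypes: np.ndarray, config: SimConfig, method: str = "snp-effects"):
    """Generate a long-format phenotype table plus its ground truth.

    ``method`` selects how genetic coefficients are drawn: "snp-effects"
    (default, scales to any N) or "cholesky" (direct MVN with covariance
    A (x) Kg; O(N^3), intended for small-N equivalence checks).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    kg, ki = config.k_g, config.k_i

    W = _standardize_columns(G)
    A = (W @ W.T) / m

    if kg == 0:
        alpha_g = np.zeros((n, 0))
        U = None
    elif not np.any(config.Kg):
        alpha_g = np.zeros((n, kg))
        U = np.zeros((m, kg))
    elif method == "snp-effects":
        Lg = np.linalg.cholesky(config.Kg + 1e-14 * np.eye(kg))
        U = rng.standard_normal((m, kg)) @ Lg.T / np.sqrt(m)
        alpha_g = W @ U
    elif method == "cholesky":
        cov = np.kron(A + 1e-8 * np.eye(n), config.Kg)
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(n * kg))
        alpha_g = (L @ rng.standard_normal(n * kg)).reshape(n, kg)
        U = None
    else:
        raise ValueError(f"unknown method {method!r}")

    if np.any(config.Ki):
        Li = np.linalg.cholesky(config.Ki + 1e-14 * np.eye(ki))
        alpha_i = rng.standard_normal((n, ki)) @ Li.T
    else:
        alpha_i = np.zeros((n, ki))

    sexes = rng.permuted(np.array(["F", "M"]).repeat((n + 1) // 2)[:n])
    waves = np.asarray(config.wave_ages, dtype=float)
    n_waves = len(waves)

    counts = np.clip(
        np.rint(rng.normal(config.mean_measurements, config.sd_measurements, size=n)),
        config.min_measurements,
        n_waves,
    ).astype(int)

    std = config.standardizer
    rows = []
    for i in range(n):
        chosen = np.sort(rng.choice(n_waves, size=counts[i], replace=False))
        if config.dropout > 0 and kg > 0:
            # genetic-value-dependent loss of post-childhood waves; keeps the
            # earliest min_measurements waves so inclusion filters still hold
            g_late = alpha_g[i] @ basis_matrix([1.0], kg).values.ravel()
            z = g_late / (np.sqrt(np.trace(config.Kg)) + 1e-12)
            p_drop = np.clip(config.dropout / (1.0 + np.exp(-z)), 0.0, 0.95)
            late = waves[chosen] > 7.0
            drop = late & (rng.uniform(size=counts[i]) < p_drop)
            keep = ~drop
            if keep.sum() < config.min_measurements:
                keep[: config.min_measurements] = True
            chosen = chosen[keep]
        ages = waves[chosen] + rng.normal(0.0, config.wave_jitter_sd, size=len(chosen))
        ages = np.clip(ages, std.min_age, std.max_age)
        ms = std.standardize(ages)
        phi_f = basis_matrix(ms, 4).values
        phi_g = basis_matrix(ms, kg).values if kg > 0 else np.zeros((len(ms), 0))
        phi_i = basis_matrix(ms, ki).values
        src = np.where(
            rng.uniform(size=len(ms)) < config.questionnaire_prob,
            "questionnaire", "clinic",
        )
        mu = phi_f @ config.fixed_curve[sexes[i]]
        mu = mu + config.source_offset * (src == "questionnaire")
        y = (
            mu
            + (phi_g @ alpha_g[i] if kg > 0 else 0.0)
            + phi_i @ alpha_i[i]
            + rng.normal(0.0, np.sqrt(config.sigma2_e), size=len(ms))
        )
        for a, s, v in zip(ages, src, y):
            rows.append((f"id{i + 1:05d}", sexes[i], a, s, v))

    table = pd.DataFrame(rows, columns=["iid", "sex", "age", "source", "log_bmi"])
    table["bmi"] = np.exp(table["log_bmi"])
    truth = SimTruth(
        alpha_g=alpha_g,
        alpha_i=alpha_i,
        snp_effects=U,
        grm=A,
        allele_freq=G.mean(axis=0) / 2.0,
        config=config,
    )
    return table, truth


def simulate_adult_pgs_weights(
    truth: SimTruth,
    target_r2: float = 0.16,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-SNP weights emulating an external adult-trait PGS.

    The true weight of each SNP is its effect projected onto the age-18
    genetic value direction phi(m = 1); independent Gaussian noise is added
    and scaled so the resulting score explains ``target_r2`` of the simulated
    age-18 phenotypic variance in expectation.  ``target_r2 = None`` (or 0
    noise) returns the noise-free weights.
    """
    if truth.snp_effects is None:
        raise ValueError("truth lacks per-SNP effects (use the snp-effects simulation route)")
    cfg = truth.config
    if target_r2 is not None and target_r2 < 0:
        raise ValueError("target_r2 must be non-negative")
    rng = np.random.default_rng(seed)
    m = truth.snp_effects.shape[0]
    phi18_g = basis_matrix([1.0], cfg.k_g).values.ravel()
    phi18_i = basis_matrix([1.0], cfg.k_i).values.ravel()
    w_true = truth.snp_effects @ phi18_g

    var_g18 = float(phi18_g @ cfg.Kg @ phi18_g)
    var_p18 = var_g18 + float(phi18_i @ cfg.Ki @ phi18_i) + cfg.sigma2_e
    if target_r2 is None or target_r2 == 0:
        noise_sd = 0.0
    else:
        max_r2 = var_g18 / var_p18
        if target_r2 >= max_r2:
            raise ValueError(
                f"target_r2 {target_r2} exceeds the age-18 heritability {max_r2:.3f}"
            )
        # R^2 = var_g18^2 / ((var_g18 + v_noise) var_p18)  =>  solve for v_noise
        v_noise = var_g18**2 / (target_r2 * var_p18) - var_g18
        noise_sd = np.sqrt(v_noise / m)
    w_std = w_true + rng.normal(0.0, noise_sd, size=m)
    # convert effects on standardized dosages to per-allele-count weights
    p = truth.allele_freq
    sd = np.sqrt(2.0 * p * (1.0 - p))
    sd[sd == 0] = 1.0
    return pd.DataFrame(
        {"snp": [f"snp{i + 1}" for i in range(m)], "a1": "A", "weight": w_std / sd}
    )
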