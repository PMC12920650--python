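import numpy as np
import pandas as pd
import pytest

from helpers import (
    dense_reml_loglik,
    effective_A,
    greml_two_component_oracle,
    make_cohort,
    polymorphic_genotypes,
)
from longrrm.basis import basis_matrix
from longrrm.reml import (
    RRMSpec,
    VarianceParams,
    build_design,
    compare_models,
    fit_heterogeneous_residual,
    fit_pgs_adjusted,
    fit_reduced,
    reml_fit,
    reml_loglik,
)
from longrrm.simulate import (
    SimConfig,
    default_kg,
    default_ki,
    simulate_adult_pgs_weights,
    simulate_cohort,
)
from longrrm.surfaces import compute_surfaces


class TestBuildDesign:
    def test_fixed_effect_column_count(self, small_cohort):
        pheno, _, _, _ = small_cohort
        des = build_design(pheno, RRMSpec())
        # 2 sexes x 4 polynomial terms + source indicator
        assert des.X.shape[1] == 9

    def test_phi_row_at_mid_age(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(
            {
                "iid": np.repeat(["a", "b", "c"], 4),
                "sex": np.repeat(["F", "M", "F"], 4),
                "age": [9.5, 2.0, 5.0, 12.0] + list(rng.uniform(1, 18, 8)),
                "source": ["clinic", "questionnaire"] * 6,
                "log_bmi": rng.normal(2.8, 0.1, 12),
            }
        )
        des = build_design(t, RRMSpec(k_g=3, k_i=3))
        ages_a = np.sort(t.loc[t["iid"] == "a", "age"].to_numpy())
        idx = int(np.argwhere(ages_a == 9.5)[0, 0])
        np.testing.assert_allclose(
            des.Phi_g[idx], basis_matrix([0.0], 3).values[0], atol=1e-12
        )

    def test_row_permutation_invariance(self, small_cohort):
        pheno, _, grm, _ = small_cohort
        des1 = build_design(pheno, RRMSpec(k_g=2, k_i=2))
        shuffled = pheno.sample(frac=1.0, random_state=1)
        des2 = build_design(shuffled, RRMSpec(k_g=2, k_i=2))
        vp = VarianceParams(Kg=default_kg()[:2, :2], Ki=default_ki()[:2, :2], sigma2_e=[0.004])
        assert reml_loglik(vp, des1, grm) == reml_loglik(vp, des2, grm)

    def test_missing_grm_id_error(self, small_cohort):
        pheno, _, _, _ = small_cohort
        with pytest.raises(ValueError, match="absent from GRM"):
            build_design(pheno, RRMSpec(), grm_ids=["nobody"])

    def test_rank_deficiency_reported(self):
        # all-clinic data makes the source indicator a zero column
        t = pd.DataFrame(
            {
                "iid": np.repeat([f"i{j}" for j in range(5)], 4),
                "sex": "F",
                "age": np.tile([2.0, 6.0, 10.0, 14.0], 5),
                "source": "clinic",
                "log_bmi": 2.8,
            }
        )
        with pytest.raises(ValueError, match="source"):
            build_design(t, RRMSpec())

    def test_ages_outside_window_rejected(self):
        t = pd.DataFrame(
            {"iid": ["a"], "sex": ["F"], "age": [25.0], "source": ["clinic"], "log_bmi": [3.0]}
        )
        with pytest.raises(ValueError, match="window"):
            build_design(t, RRMSpec())


class TestRemlLoglik:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_ind = int(rng.integers(3, 8))
        pheno, _, grm, _ = make_cohort(
            n=n_ind, m=80, seed=seed, mean_measurements=4, sd_measurements=1,
            maf_range=(0.3, 0.5),
        )
        kg = int(rng.integers(1, 3))
        ki = int(rng.integers(1, 3))
        des = build_design(pheno, RRMSpec(k_g=kg, k_i=ki))
        vp = VarianceParams(
            Kg=default_kg()[:kg, :kg] * rng.uniform(0.5, 2.0),
            Ki=default_ki()[:ki, :ki] * rng.uniform(0.5, 2.0),
            sigma2_e=[rng.uniform(0.002, 0.01)],
        )
        ours = reml_loglik(vp, des, grm)
        oracle = dense_reml_loglik(vp, des, effective_A(grm, des.ids))
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_zero_variances_reduce_to_ols(self, small_cohort):
        pheno, _, grm, _ = small_cohort
        des = build_design(pheno, RRMSpec(k_g=3, k_i=3))
        s2 = 0.02
        vp = VarianceParams(Kg=np.zeros((3, 3)), Ki=np.zeros((3, 3)), sigma2_e=[s2])
        ours = reml_loglik(vp, des, grm)
        # closed-form REML for V = s2 * I
        X, y = des.X, des.y
        n, p = X.shape
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        rss = float(y @ (np.eye(n) - H) @ y)
        expect = -0.5 * (
            (n - p) * np.log(2 * np.pi)
            + (n - p) * np.log(s2)
            + np.linalg.slogdet(X.T @ X)[1]
            + rss / s2
        )
        assert ours == pytest.approx(expect, abs=1e-6)

    def test_scale_equivariance(self, small_cohort):
        pheno, _, grm, _ = small_cohort
        des = build_design(pheno, RRMSpec(k_g=2, k_i=2))
        vp = VarianceParams(Kg=default_kg()[:2, :2], Ki=default_ki()[:2, :2], sigma2_e=[0.004])
        base = reml_loglik(vp, des, grm)
        c = 3.7
        scaled = pheno.copy()
        scaled["log_bmi"] = scaled["log_bmi"] * c
        des2 = build_design(scaled, RRMSpec(k_g=2, k_i=2))
        vp2 = VarianceParams(
            Kg=vp.Kg * c**2, Ki=vp.Ki * c**2, sigma2_e=vp.sigma2_e * c**2
        )
        n, p = des.X.shape
        assert reml_loglik(vp2, des2, grm) == pytest.approx(
            base - (n - p) * np.log(c), abs=1e-6
        )


@pytest.fixture(scope="module")
def fitted(small_cohort):
    pheno, truth, grm, _ = small_cohort
    des = build_design(pheno, RRMSpec(k_g=3, k_i=3))
    return des, reml_fit(des, grm), grm


class TestRemlFit:
    def test_converged_and_monotone(self, fitted):
        _, fit, _ = fitted
        assert fit.converged
        diffs = np.diff(fit.logl_trace)
        assert np.all(diffs > -1e-6)

    def test_sampling_cov_psd(self, fitted):
        _, fit, _ = fitted
        w = np.linalg.eigvalsh(fit.sampling_cov)
        assert w.min() > -1e-10 * max(w.max(), 1)

    def test_aic_formula(self, fitted):
        _, fit, _ = fitted
        assert fit.aic == pytest.approx(-2 * fit.logl + 2 * 13)

    def test_blup_shapes(self, fitted):
        des, fit, _ = fitted
        assert fit.blup_g.shape == (des.n_individuals, 3)
        assert fit.blup_i.shape == (des.n_individuals, 3)

    def test_shift_equivariance(self, small_cohort):
        # adding a constant to y moves only the sex-intercept coefficients
        pheno, _, grm, _ = small_cohort
        spec = RRMSpec(k_g=2, k_i=2)
        fit1 = reml_fit(build_design(pheno, spec), grm)
        shifted = pheno.copy()
        shifted["log_bmi"] += 5.0
        fit2 = reml_fit(build_design(shifted, spec), grm)
        np.testing.assert_allclose(
            fit1.varparams.pack(), fit2.varparams.pack(), rtol=1e-3, atol=1e-9
        )
        moved = np.abs(fit1.b - fit2.b)
        names = np.array(fit1.x_names)
        is_intercept = np.array([nm.endswith("phi0") for nm in names])
        # phi0 is constant sqrt(1/2): intercepts shift by 5 / sqrt(1/2)
        np.testing.assert_allclose(moved[is_intercept], 5.0 / np.sqrt(0.5), atol=1e-4)
        assert np.all(moved[~is_intercept] < 1e-4)

    def test_greml_special_case(self):
        # single record each, k_g = 1, k_i = 0 vs direct 2-component oracle
        pheno, _, grm, _ = make_cohort(n=120, m=600, seed=21)
        one = pheno.groupby("iid", as_index=False).first()
        spec = RRMSpec(k_f=4, k_g=1, k_i=0)
        des = build_design(one, spec)
        fit = reml_fit(des, grm)
        lam11_sq = 0.5  # phi0^2
        sa, se, _ = greml_two_component_oracle(des.y, des.X, effective_A(grm, des.ids))
        assert fit.varparams.Kg[0, 0] * lam11_sq == pytest.approx(sa, abs=1e-4)
        assert fit.varparams.sigma2_e[0] == pytest.approx(se, abs=1e-4)


class TestCompareModels:
    def test_identical_fits(self, fitted):
        _, fit, _ = fitted
        res = compare_models(fit, fit)
        assert res["lrt"] == 0.0
        assert res["p"] == 1.0

    def test_df_counting(self, small_cohort):
        pheno, _, grm, _ = small_cohort
        f3 = reml_fit(build_design(pheno, RRMSpec(k_g=3, k_i=3)), grm)
        f2 = reml_fit(build_design(pheno, RRMSpec(k_g=2, k_i=3)), grm)
        res = compare_models(f3, f2)
        assert res["df"] == 3  # one variance + two covariances
        assert res["boundary_caveat"]

    def test_different_fixed_effects_rejected(self, small_cohort):
        pheno, _, grm, _ = small_cohort
        f1 = reml_fit(build_design(pheno, RRMSpec(k_g=2, k_i=2)), grm)
        nosource = reml_fit(
            build_design(pheno, RRMSpec(k_g=2, k_i=2, covariates=("sex",))), grm
        )
        with pytest.raises(ValueError, match="fixed effects"):
            compare_models(f1, nosource)

    def test_selects_quadratic_genetic_model(self):
        # strong quadratic genetic signal: k_g = 3 should beat k_g = 2
        wins = 0
        for rep in range(3):
            K = np.diag([0.009, 0.004, 0.006])
            pheno, _, grm, _ = make_cohort(n=150, m=400, seed=50 + rep, Kg=K)
            full = reml_fit(build_design(pheno, RRMSpec(k_g=3, k_i=3)), grm)
            red = reml_fit(build_design(pheno, RRMSpec(k_g=2, k_i=3)), grm)
            res = compare_models(full, red)
            if res["delta_aic"] < 0 and res["p"] < 0.05:
                wins += 1
        assert wins >= 2


class TestFitReduced:
    def test_nested_likelihood(self, small_cohort, fitted):
        pheno, _, _, _ = small_cohort
        _, full, _ = fitted
        red = fit_reduced(build_design(pheno, RRMSpec(k_g=0, k_i=3)))
        assert red.logl <= full.logl + 1e-6

    def test_intercept_blup_tracks_individual_means(self, small_cohort):
        pheno, _, _, _ = small_cohort
        red = fit_reduced(build_design(pheno, RRMSpec(k_g=0, k_i=3)))
        means = pheno.groupby("iid")["log_bmi"].mean().loc[red.ids].to_numpy()
        r = np.corrcoef(red.blup_i[:, 0], means)[0, 1]
        assert r > 0.9

    def test_deterministic(self, small_cohort):
        pheno, _, _, _ = small_cohort
        des = build_design(pheno, RRMSpec(k_g=0, k_i=3))
        r1 = fit_reduced(des)
        r2 = fit_reduced(des)
        np.testing.assert_array_equal(r1.blup_i, r2.blup_i)

    def test_requires_zero_kg(self, small_cohort):
        pheno, _, _, _ = small_cohort
        with pytest.raises(ValueError):
            fit_reduced(build_design(pheno, RRMSpec(k_g=1, k_i=3)))


class TestPgsAdjusted:
    def test_zero_weights_match_unadjusted_variances(self, small_cohort):
        pheno, truth, grm, G = small_cohort
        spec = RRMSpec(k_g=2, k_i=2)
        base = reml_fit(build_design(pheno, spec), grm)
        ids = sorted(pheno["iid"].unique())
        pgs = dict(zip(ids, np.zeros(len(ids))))
        spec_p = RRMSpec(k_g=2, k_i=2, pgs_interactions=True)
        with pytest.raises(ValueError, match="rank-deficient"):
            # all-zero PGS columns are rank deficient by construction
            build_design(pheno, spec_p, pgs=pgs)

    def test_heritability_attenuates_at_late_ages(self):
        # a PGS built from the true SNP effects should soak up late-age
        # genetic variance (directional, replicate-averaged)
        drops, infancy_drops = [], []
        for rep in range(3):
            G = polymorphic_genotypes(150, 500, seed=70 + rep)
            cfg = SimConfig(n_individuals=150, n_snps=G.shape[1], seed=70 + rep)
            pheno, truth = simulate_cohort(G, cfg)
            from longrrm.grm import GenotypePanel, build_grm

            grm = build_grm(
                GenotypePanel(iids=sorted(pheno["iid"].unique()), snps=None, genotypes=G)
            )
            w = simulate_adult_pgs_weights(truth, target_r2=0.16, seed=rep)
            score = G @ w["weight"].to_numpy()
            pgs = dict(zip(sorted(pheno["iid"].unique()), score))
            base = reml_fit(build_design(pheno, RRMSpec(k_g=3, k_i=3)), grm)
            adj = fit_pgs_adjusted(
                build_design(pheno, RRMSpec(k_g=3, k_i=3, pgs_interactions=True), pgs=pgs),
                grm,
            )
            ages = np.array([1.0, 2.0, 3.0, 18.0])
            s_base = compute_surfaces(base, ages=ages, with_se=False)
            s_adj = compute_surfaces(adj, ages=ages, with_se=False)
            drops.append(s_base.Vg[3, 3] - s_adj.Vg[3, 3])
            infancy_drops.append(np.mean(np.diag(s_base.Vg)[:3] - np.diag(s_adj.Vg)[:3]))
        assert np.mean(drops) > 0  # age-18 genetic variance falls
        assert np.mean(infancy_drops) < np.mean(drops)  # infancy less affected

    def test_missing_pgs_errors(self, small_cohort):
        pheno, _, grm, _ = small_cohort
        spec = RRMSpec(k_g=2, k_i=2, pgs_interactions=True)
        with pytest.raises(ValueError, match="PGS"):
            build_design(pheno, spec, pgs={"only_one_id": 1.0})


class TestHeterogeneousResidual:
    def test_seventeen_bins_by_construction(self, small_cohort):
        pheno, _, _, _ = small_cohort
        des = build_design(pheno, RRMSpec(k_g=3, k_i=3, residual_structure="per-year"))
        # bins cover the sampled ages; the full window would give 17
        assert des.n_bins <= 17
        assert RRMSpec(residual_structure="per-year").n_variance_params == 12 + 17

    def test_constant_sigma_recovered_flat(self):
        pheno, _, grm, _ = make_cohort(n=120, m=400, seed=31)
        des = build_design(pheno, RRMSpec(k_g=2, k_i=2, residual_structure="per-year"))
        fit = fit_heterogeneous_residual(des, grm)
        sig = fit.varparams.sigma2_e
        bins = np.arange(len(sig))
        slope = np.polyfit(bins, sig, 1)[0]
        # no systematic trend (slope small relative to the mean level)
        assert abs(slope) * len(sig) < 1.0 * sig.mean()

    def test_step_change_recovered(self):
        G = polymorphic_genotypes(150, 400, seed=33)
        cfg = SimConfig(n_individuals=150, n_snps=G.shape[1], seed=33, sigma2_e=0.003)
        pheno, _ = simulate_cohort(G, cfg)
        rng = np.random.default_rng(33)
        late = pheno["age"] > 9
        # add extra noise after age 9: variance triples
        pheno.loc[late, "log_bmi"] += rng.normal(
            0, np.sqrt(2 * 0.003), int(late.sum())
        )
        from longrrm.grm import GenotypePanel, build_grm

        grm = build_grm(
            GenotypePanel(iids=sorted(pheno["iid"].unique()), snps=None, genotypes=G)
        )
        des = build_design(pheno, RRMSpec(k_g=2, k_i=2, residual_structure="per-year"))
        fit = fit_heterogeneous_residual(des, grm)
        sig = fit.varparams.sigma2_e
        labels = des.bin_labels
        early = [s for s, lab in zip(sig, labels) if int(lab.split()[1]) < 9]
        late_b = [s for s, lab in zip(sig, labels) if int(lab.split()[1]) > 9]
        assert np.mean(late_b) > 2.0 * np.mean(early)

    def test_requires_per_year_design(self, small_cohort):
        pheno, _, grm, _ = small_cohort
        with pytest.raises(ValueError):
            fit_heterogeneous_residual(build_design(pheno, RRMSpec()), grm)
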