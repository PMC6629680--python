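import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cystomics import (
    CohortSpec,
    ModelSpec,
    ValidationError,
    adjust_matrix,
    fit_model,
    fold_changes,
    merge_groups,
    pca_project,
    preprocess_pipeline,
    select_covariates,
    simulate_cohort,
)
from cystomics.cohort import contrast_effect_table
from cystomics.hierarchical import ConvergenceWarning, PosteriorDraws

GROUPS4 = ("SCN", "LGD", "HGD", "Cancer")


class TestFitModel:
    def test_sum_to_zero_every_draw(self, small_draws):
        assert np.abs(small_draws.phi.sum(axis=1)).max() < 1e-10
        assert np.abs(small_draws.lam.sum(axis=1)).max() < 1e-10
        assert np.abs(small_draws.eta.sum(axis=1)).max() < 1e-10  # over groups

    def test_positive_scales_every_draw(self, small_draws):
        for arr in (
            small_draws.sigma,
            small_draws.alpha,
            small_draws.beta,
            small_draws.zeta,
            small_draws.omega,
        ):
            assert (arr > 0).all()

    def test_seed_determinism(self, small_pre, small_cohort):
        kwargs = dict(
            spec=ModelSpec(groups=GROUPS4),
            n_draws=200,
            n_chains=2,
            warmup=100,
            seed=5,
        )
        a = fit_model(small_pre, small_cohort.clinical, **kwargs)
        b = fit_model(small_pre, small_cohort.clinical, **kwargs)
        assert np.array_equal(a.eta, b.eta)
        assert np.array_equal(a.sigma, b.sigma)

    def test_sigma_recovered(self, small_draws, small_cohort):
        true = small_cohort.spec.sigma
        lo, hi = np.percentile(small_draws.sigma, [1, 99])
        assert lo < true < hi

    def test_null_eta_recovery(self):
        # [DERIVED] null cohort: every posterior eta mean within 3 sds of 0
        spec = CohortSpec(
            n_per_group={g: 10 for g in GROUPS4},
            m_molecules=20,
            sigma=0.5,
            q_cens=0.0,
            seed=41,
        )
        cohort = simulate_cohort(spec)
        pre = preprocess_pipeline(cohort.concentrations, cohort.clinical, seed=42)
        draws = fit_model(
            pre, cohort.clinical, spec=ModelSpec(groups=GROUPS4),
            n_draws=1000, n_chains=2, warmup=400, seed=43,
        )
        z = draws.eta.mean(axis=0) / draws.eta.std(axis=0)
        assert np.abs(z).max() < 3.0

    def test_gamma_recovery(self):
        # [DERIVED] known age slope 0.05 for every molecule: CrI covers
        # the truth for >= 90% of molecules
        m = 30
        spec = CohortSpec(
            n_per_group={"SCN": 20, "LGD": 20},
            m_molecules=m,
            covariate_effects={"age": np.full(m, 0.05)},
            sigma=0.4,
            q_cens=0.0,
            seed=51,
        )
        cohort = simulate_cohort(spec)
        pre = preprocess_pipeline(cohort.concentrations, cohort.clinical, seed=52)
        draws = fit_model(
            pre, cohort.clinical,
            spec=ModelSpec(groups=("SCN", "LGD"), covariates=("age", "bmi")),
            n_draws=1000, n_chains=2, warmup=400, seed=53,
        )
        age_draws = draws.gamma[:, 0, :]  # (D, m)
        lo, hi = np.percentile(age_draws, [2.5, 97.5], axis=0)
        coverage = ((lo <= 0.05) & (0.05 <= hi)).mean()
        assert coverage >= 0.9

    def test_convergence_warning_raised_at_tight_threshold(
        self, small_pre, small_cohort
    ):
        spec = ModelSpec(groups=GROUPS4, rhat_threshold=1.0)
        with pytest.warns(ConvergenceWarning):
            fit_model(
                small_pre, small_cohort.clinical, spec=spec,
                n_draws=100, n_chains=2, warmup=50, seed=9,
            )

    def test_nonfinite_matrix_rejected(self, small_pre, small_cohort):
        broken = small_pre
        vals = broken.values.copy()
        vals.iloc[0, 0] = np.inf
        import dataclasses

        bad = dataclasses.replace(broken, values=vals)
        with pytest.raises(ValidationError):
            fit_model(bad, small_cohort.clinical, n_draws=40, n_chains=2,
                      warmup=10, seed=1)


class TestFoldChanges:
    def test_same_group_rejected(self, small_draws):
        with pytest.raises(ValidationError):
            fold_changes(small_draws, "SCN", "SCN")

    def test_unknown_group_rejected(self, small_draws):
        with pytest.raises(ValidationError):
            fold_changes(small_draws, "SCN", "MCN")

    def test_identical_eta_gives_unit_fc(self, small_draws):
        import dataclasses

        degenerate = dataclasses.replace(
            small_draws, eta=np.zeros_like(small_draws.eta)
        )
        fct = fold_changes(degenerate, "SCN", "LGD")
        assert np.allclose(fct.table["fc"], 1.0)
        assert np.allclose(fct.table["lo95"], 1.0)
        assert np.allclose(fct.table["hi95"], 1.0)
        assert not fct.table["significant"].any()

    def test_interval_orders_and_flag_consistency(self, small_draws):
        fct = fold_changes(small_draws, "SCN", "Cancer").table
        assert (fct["lo95"] <= fct["fc"]).all()
        assert (fct["fc"] <= fct["hi95"]).all()
        expected_flag = (fct["lo95"] > 1.0) | (fct["hi95"] < 1.0)
        assert (fct["significant"] == expected_flag).all()

    def test_antisymmetry(self, small_draws):
        ab = fold_changes(small_draws, "LGD", "HGD").table
        ba = fold_changes(small_draws, "HGD", "LGD").table
        assert np.allclose(ab["fc"], 1.0 / ba["fc"])
        assert np.allclose(ab["lo95"], 1.0 / ba["hi95"])
        assert np.allclose(ab["hi95"], 1.0 / ba["lo95"])

    def test_contrast_recovery_median_near_two(self):
        # [DERIVED] truth contrast log 2 at n = 30/group, m = 100:
        # recovered median fold change lands in [1.7, 2.3]
        # background effects drawn from the model's own law so the
        # hierarchical prior is well specified and shrinkage stays mild
        m = 100
        rng = np.random.default_rng(161)
        eta = rng.normal(0, 0.6, (2, m))
        eta -= eta.mean(axis=0, keepdims=True)
        eta[:, :10] = 0.0
        eta[0, :10] = np.log(2.0) / 2
        eta[1, :10] = -np.log(2.0) / 2
        spec = CohortSpec(
            n_per_group={"A": 30, "B": 30}, m_molecules=m,
            effect_table=eta, sigma=0.5, hyper_sds=(0.1, 1.0),
            q_cens=0.0, seed=162,
        )
        cohort = simulate_cohort(spec)
        pre = preprocess_pipeline(cohort.concentrations, cohort.clinical, seed=163)
        draws = fit_model(
            pre, cohort.clinical, spec=ModelSpec(groups=("A", "B")),
            n_draws=1000, n_chains=2, warmup=500, seed=164,
        )
        fct = fold_changes(draws, "A", "B").table
        assert 1.7 <= np.median(fct["fc"].to_numpy()[:10]) <= 2.3

    def test_null_cohort_significance_rate(self):
        # eta = 0 truth: significance flags at <= 10% of molecules
        spec = CohortSpec(
            n_per_group={g: 8 for g in GROUPS4}, m_molecules=40,
            sigma=0.5, q_cens=0.0, seed=71,
        )
        cohort = simulate_cohort(spec)
        pre = preprocess_pipeline(cohort.concentrations, cohort.clinical, seed=72)
        draws = fit_model(
            pre, cohort.clinical, spec=ModelSpec(groups=GROUPS4),
            n_draws=1000, n_chains=2, warmup=400, seed=73,
        )
        fct = fold_changes(draws, "SCN", "Cancer").table
        assert fct["significant"].mean() <= 0.10


class TestMergeGroups:
    def test_hgd_cancer_merge_reduces_k(self, small_cohort):
        merged = merge_groups(small_cohort.clinical, ["HGD", "Cancer"], "HGD/Cancer")
        assert set(merged["group"]) == {"SCN", "LGD", "HGD/Cancer"}

    def test_ipmn_merge_gives_two_groups(self, small_cohort):
        merged = merge_groups(
            small_cohort.clinical, ["LGD", "HGD", "Cancer"], "IPMN"
        )
        assert set(merged["group"]) == {"SCN", "IPMN"}

    def test_single_label_identity(self, small_cohort):
        merged = merge_groups(small_cohort.clinical, ["LGD"], "LGD2")
        assert set(merged["group"]) == {"SCN", "LGD2", "HGD", "Cancer"}
        assert (merged["group"] == "LGD2").sum() == (
            small_cohort.clinical["group"] == "LGD"
        ).sum()

    def test_collision_with_existing_label(self, small_cohort):
        with pytest.raises(ValidationError):
            merge_groups(small_cohort.clinical, ["HGD", "Cancer"], "SCN")

    def test_unknown_label(self, small_cohort):
        with pytest.raises(ValidationError):
            merge_groups(small_cohort.clinical, ["MCN"], "X")


class TestAdjustMatrix:
    def test_rows_standardized(self, small_pre, small_cohort, small_draws):
        adj = adjust_matrix(small_pre, small_cohort.clinical, small_draws)
        arr = adj.values.to_numpy()
        assert np.allclose(arr.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(arr.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_zero_gamma_reduces_to_zscore(self, small_pre, small_cohort, small_draws):
        import dataclasses

        from cystomics.matrix import zscore_rows

        zero = dataclasses.replace(
            small_draws, gamma=np.zeros_like(small_draws.gamma)
        )
        adj = adjust_matrix(small_pre, small_cohort.clinical, zero)
        expected = zscore_rows(small_pre.values)
        assert np.allclose(adj.values.to_numpy(), expected.to_numpy())

    def test_age_driven_separation_removed(self):
        # [DERIVED] groups separated only through an age effect: the
        # between/within group variance of PC1 drops after adjustment.
        m = 30
        spec = CohortSpec(
            n_per_group={"SCN": 15, "LGD": 15},  # disjoint age ranges
            m_molecules=m,
            covariate_effects={"age": np.full(m, 0.08)},
            sigma=0.4,
            q_cens=0.0,
            seed=81,
        )
        cohort = simulate_cohort(spec)
        pre = preprocess_pipeline(cohort.concentrations, cohort.clinical, seed=82)
        draws = fit_model(
            pre, cohort.clinical,
            spec=ModelSpec(groups=("SCN", "LGD"), covariates=("age",)),
            n_draws=600, n_chains=2, warmup=300, seed=83,
        )

        def separation(values):
            from cystomics.matrix import AdjustedMatrix, zscore_rows

            adj = AdjustedMatrix(values=zscore_rows(values), classes=pre.classes)
            pc1 = pca_project(adj, 1).scores["PC1"]
            g = cohort.clinical.loc[pc1.index, "group"]
            grand = pc1.mean()
            between = sum(
                len(s) * (s.mean() - grand) ** 2 for _, s in pc1.groupby(g)
            )
            within = sum(((s - s.mean()) ** 2).sum() for _, s in pc1.groupby(g))
            return between / within

        before = separation(pre.values)
        adj = adjust_matrix(pre, cohort.clinical, draws)
        from cystomics.matrix import AdjustedMatrix

        pc1 = pca_project(adj, 1).scores["PC1"]
        g = cohort.clinical.loc[pc1.index, "group"]
        grand = pc1.mean()
        between = sum(len(s) * (s.mean() - grand) ** 2 for _, s in pc1.groupby(g))
        within = sum(((s - s.mean()) ** 2).sum() for _, s in pc1.groupby(g))
        after = between / within
        assert after < before

    def test_missing_covariate_errors(self, small_pre, small_cohort):
        import dataclasses

        draws = fit_model(
            small_pre, small_cohort.clinical,
            spec=ModelSpec(groups=GROUPS4, covariates=()),
            n_draws=100, n_chains=2, warmup=50, seed=2,
        )
        with pytest.raises(ValidationError):
            adjust_matrix(small_pre, small_cohort.clinical, draws)


class TestSelectCovariates:
    def test_empty_only_candidate_returns_empty(self, small_pre, small_cohort):
        chosen, scores = select_covariates(
            small_pre, small_cohort.clinical, [()],
            n_draws=100, n_chains=2, warmup=50, seed=3,
        )
        assert chosen == ()
        assert len(scores) == 1

    def test_true_age_effect_selected(self):
        # [DERIVED] strong age effect, no bmi effect: {age} outranks both
        # the empty set and {bmi}
        # slopes vary by molecule: a molecule-common slope is absorbable
        # by the per-sample effects, so only heterogeneous slopes carry
        # out-of-sample predictive signal
        m = 15
        slopes = np.linspace(-0.08, 0.08, m)
        spec = CohortSpec(
            n_per_group={"SCN": 15, "LGD": 15},
            m_molecules=m,
            covariate_effects={"age": slopes},
            sigma=0.4,
            q_cens=0.0,
            seed=91,
        )
        cohort = simulate_cohort(spec)
        pre = preprocess_pipeline(cohort.concentrations, cohort.clinical, seed=92)
        chosen, scores = select_covariates(
            pre, cohort.clinical, [(), ("age",), ("bmi",)],
            n_draws=600, n_chains=2, warmup=300, seed=93,
        )
        assert chosen == ("age",)
        tbl = dict(zip(scores["covariates"], scores["elpd_loo"]))
        assert tbl[("age",)] > tbl[()]
        assert tbl[("age",)] > tbl[("bmi",)]

    def test_noise_covariate_adds_no_real_score(self):
        m = 12
        spec = CohortSpec(
            n_per_group={"SCN": 12, "LGD": 12},
            m_molecules=m,
            covariate_effects={"age": np.linspace(-0.06, 0.06, m)},
            sigma=0.4,
            q_cens=0.0,
            seed=95,
        )
        cohort = simulate_cohort(spec)
        clin = cohort.clinical.copy()
        rng = np.random.default_rng(96)
        clin["noise"] = rng.standard_normal(len(clin))
        pre = preprocess_pipeline(cohort.concentrations, clin, seed=97)
        _, scores = select_covariates(
            pre, clin, [("age",), ("age", "noise")],
            n_draws=600, n_chains=2, warmup=300, seed=98,
        )
        tbl = dict(zip(scores["covariates"], scores["elpd_loo"]))
        gain = tbl[("age", "noise")] - tbl[("age",)]
        mc_error = 3.0 * scores["se"].max()
        assert gain <= mc_error

    def test_unknown_covariate_rejected(self, small_pre, small_cohort):
        with pytest.raises(ValidationError):
            select_covariates(
                small_pre, small_cohort.clinical, [("shoe_size",)],
                n_draws=40, n_chains=2, warmup=10, seed=1,
            )


class TestCalibration:
    def test_simulation_based_calibration_theta(self):
        # Prior draw -> forward simulate -> fit -> rank of the truth
        # among thinned posterior draws; uniform under a correct sampler.
        nu, A = 3.0, 10.0
        n, m, k = 6, 4, 2
        reps, keep, thin = 60, 40, 8
        rng = np.random.default_rng(2024)
        group_idx = np.array([0, 0, 0, 1, 1, 1])
        ranks = []
        for _ in range(reps):
            theta = stats.t.rvs(nu, scale=A, random_state=rng)
            alpha, beta, sigma = np.abs(
                stats.t.rvs(nu, scale=A, size=3, random_state=rng)
            )
            zeta = np.abs(stats.t.rvs(nu, scale=A, size=k, random_state=rng))
            phi = rng.normal(0, alpha, n)
            lam = rng.normal(0, beta, m)
            eta = rng.normal(0, zeta[:, None], (k, m))
            y = (
                theta
                + phi[:, None]
                + lam[None, :]
                + eta[group_idx]
                + rng.normal(0, sigma, (n, m))
            )
            pre = _as_pre(y)
            clin = pd.DataFrame(
                {"group": ["A"] * 3 + ["B"] * 3}, index=pre.samples
            )
            draws = fit_model(
                pre, clin,
                spec=ModelSpec(groups=("A", "B"), covariates=()),
                n_draws=keep, n_chains=1, warmup=300, thin=thin,
                seed=int(rng.integers(2**31)),
            )
            # compare like with like: sweep the simulated truth too
            theta_swept = theta + phi.mean() + lam.mean() + eta.mean()
            ranks.append(int((draws.theta < theta_swept).sum()))
        u = (np.array(ranks) + rng.random(reps)) / (keep + 1)
        counts, _ = np.histogram(u, bins=5, range=(0, 1))
        chi2 = ((counts - reps / 5) ** 2 / (reps / 5)).sum()
        p = 1.0 - stats.chi2.cdf(chi2, df=4)
        assert p > 0.01


def _as_pre(y: np.ndarray):
    """Wrap a samples x molecules array as a PreprocessedMatrix."""
    from cystomics.preprocess import PreprocessedMatrix

    n, m = y.shape
    mols = [f"mol_{j:03d}" for j in range(m)]
    samp = [f"s{i:03d}" for i in range(n)]
    values = pd.DataFrame(y.T, index=mols, columns=samp)
    return PreprocessedMatrix(
        values=values,
        classes=pd.Series(["TAG"] * m, index=mols),
        imputed_mask=values.isna(),
        dropped_molecules=pd.DataFrame(),
        per_molecule_min_observed=values.min(axis=1),
    )
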