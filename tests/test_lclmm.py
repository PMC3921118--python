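"""Latent class linear mixed model: likelihood, EM fit, BIC, posteriors."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from lctraj.lclmm import (
    LCLMMParams,
    LCLMMSpec,
    bic,
    build_design,
    fit_lclmm,
    marginal_loglik,
    posterior_probs,
    select_num_classes,
)
from lctraj.lmm import profile_ml_lmm
from lctraj.simulate import SyntheticConfig, generate_cohort


class TestBuildDesign:
    def test_polynomial_expansion(self, small_cohort):
        _, dataset, _ = small_cohort
        design = build_design(dataset, LCLMMSpec(n_classes=1, degree=3))
        b = design.batches[0]
        t = b.X2[..., 1]
        assert np.allclose(b.X2[..., 2], t**2)
        assert np.allclose(b.X2[..., 3], t**3)
        # intercept column is 1 exactly at real observations
        assert np.all(b.X2[..., 0][b.mask] == 1.0)

    def test_degree_one_design(self, small_cohort):
        _, dataset, _ = small_cohort
        design = build_design(dataset, LCLMMSpec(n_classes=1, degree=1))
        assert design.batches[0].X2.shape[-1] == 2

    def test_phase_dummies_reference_earliest(self, small_cohort):
        _, dataset, _ = small_cohort
        design = build_design(dataset, LCLMMSpec(n_classes=1))
        # phases 3,5,7,9 -> indicators for 5,7,9 only
        assert set(design.shared_names) == {"age_t0", "sex", "phase_5", "phase_7", "phase_9"}

    def test_subject_without_outcome_excluded(self, small_cohort):
        _, dataset, _ = small_cohort
        records = dataset.records.copy()
        victim = records["subject_id"].iloc[0]
        records.loc[records["subject_id"] == victim, "bmi"] = np.nan
        design = build_design(records, LCLMMSpec(n_classes=1))
        assert victim not in set(design.subject_ids)


class TestMarginalLoglik:
    def test_matches_direct_multivariate_normal(self, tiny_design, tiny_params):
        design, _ = tiny_design
        ll = marginal_loglik(tiny_params, design)
        direct = 0.0
        b = design.batches[0]
        for i in range(len(b.ids)):
            m = int(b.mask[i].sum())
            mu = b.X2[i][:m] @ tiny_params.delta[0] + b.X1[i][:m] @ tiny_params.beta
            V = (
                b.Z[i][:m] @ tiny_params.B @ b.Z[i][:m].T
                + tiny_params.sigma2 * np.eye(m)
            )
            direct += multivariate_normal.logpdf(b.Y[i][:m], mu, V)
        assert ll == pytest.approx(direct, abs=1e-6)

    def test_degenerate_mixture_equals_single_class(self, tiny_design, tiny_params):
        design, _ = tiny_design
        ll1 = marginal_loglik(tiny_params, design)
        two = LCLMMParams(
            pi=np.array([1.0 - 1e-300, 1e-300]),
            delta=np.vstack([tiny_params.delta, tiny_params.delta + 5.0]),
            beta=tiny_params.beta,
            B=tiny_params.B,
            sigma2=tiny_params.sigma2,
        )
        assert marginal_loglik(two, design) == pytest.approx(ll1, abs=1e-8)

    def test_two_class_matches_monte_carlo(self, tiny_design, tiny_params):
        design, _ = tiny_design
        params = LCLMMParams(
            pi=np.array([0.6, 0.4]),
            delta=np.vstack([tiny_params.delta, tiny_params.delta + [5, 0.4, 0.01, 0]]),
            beta=tiny_params.beta,
            B=tiny_params.B,
            sigma2=tiny_params.sigma2,
        )
        ll = marginal_loglik(params, design)
        rng = np.random.default_rng(42)
        n_mc = 10**5
        draws = rng.multivariate_normal(np.zeros(2), params.B, size=n_mc)
        ll_mc, var_log = 0.0, 0.0
        b = design.batches[0]
        for i in range(len(b.ids)):
            m = int(b.mask[i].sum())
            dens = np.zeros(n_mc)
            for g, w in enumerate(params.pi):
                mu = b.X2[i][:m] @ params.delta[g] + b.X1[i][:m] @ params.beta
                resid = b.Y[i][None, :m] - mu[None, :] - draws @ b.Z[i][:m].T
                logd = -0.5 * (
                    m * np.log(2 * np.pi * params.sigma2)
                    + (resid**2).sum(axis=1) / params.sigma2
                )
                dens += w * np.exp(logd)
            est = dens.mean()
            ll_mc += np.log(est)
            var_log += (dens.std() / np.sqrt(n_mc) / est) ** 2
        assert abs(ll - ll_mc) < 3 * np.sqrt(var_log)

    def test_invalid_covariance_rejected(self, tiny_design, tiny_params):
        design, _ = tiny_design
        bad = LCLMMParams(
            pi=tiny_params.pi,
            delta=tiny_params.delta,
            beta=tiny_params.beta,
            B=np.array([[1.0, 2.0], [2.0, 1.0]]),  # indefinite
            sigma2=tiny_params.sigma2,
        )
        with pytest.raises(ValueError):
            marginal_loglik(bad, design)

    def test_label_permutation_invariance(self, tiny_design, tiny_params):
        design, _ = tiny_design
        params = LCLMMParams(
            pi=np.array([0.7, 0.3]),
            delta=np.vstack([tiny_params.delta, tiny_params.delta + 3]),
            beta=tiny_params.beta,
            B=tiny_params.B,
            sigma2=tiny_params.sigma2,
        )
        flipped = LCLMMParams(
            pi=params.pi[::-1].copy(),
            delta=params.delta[::-1].copy(),
            beta=params.beta,
            B=params.B,
            sigma2=params.sigma2,
        )
        assert marginal_loglik(params, design) == pytest.approx(
            marginal_loglik(flipped, design), abs=1e-9
        )


class TestBIC:
    def test_formula(self):
        assert bic(-100.0, 10, 50) == pytest.approx(200 + 10 * np.log(50))
        assert bic(-100.0, 1, 1) == pytest.approx(200.0)

    def test_increasing_in_parameter_count(self):
        assert bic(-100.0, 11, 50) - bic(-100.0, 10, 50) == pytest.approx(np.log(50))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bic(-100.0, 0, 50)


class TestFitLclmm:
    def test_single_class_matches_gls_profile_oracle(self, single_class_cohort):
        _, dataset, _ = single_class_cohort
        spec = LCLMMSpec(n_classes=1)
        design = build_design(dataset, spec)
        fit = fit_lclmm(design, spec, n_starts=1, tol=1e-12, max_iter=5000, polish=True)
        oracle = profile_ml_lmm(design)
        assert fit.loglik == pytest.approx(oracle.loglik, abs=1e-6)
        assert np.allclose(
            np.concatenate([fit.delta[0], fit.beta]), oracle.theta, atol=1e-3
        )

    def test_em_loglik_monotone(self, small_cohort):
        _, dataset, _ = small_cohort
        spec = LCLMMSpec(n_classes=3)
        fit = fit_lclmm(dataset, spec, n_starts=2, tol=1e-6, max_iter=150, seed=0)
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_deterministic_under_seed(self, small_cohort):
        _, dataset, _ = small_cohort
        spec = LCLMMSpec(n_classes=2)
        a = fit_lclmm(dataset, spec, n_starts=3, tol=1e-6, max_iter=100, seed=5)
        b = fit_lclmm(dataset, spec, n_starts=3, tol=1e-6, max_iter=100, seed=5)
        assert np.array_equal(a.pi, b.pi)
        assert np.array_equal(a.delta, b.delta)
        assert a.loglik == b.loglik

    def test_classes_reported_in_descending_size(self, small_cohort):
        _, dataset, _ = small_cohort
        spec = LCLMMSpec(n_classes=3)
        fit = fit_lclmm(dataset, spec, n_starts=3, tol=1e-6, max_iter=300, seed=0)
        counts = fit.class_counts.to_numpy()
        assert np.all(np.diff(counts) <= 0)

    def test_too_few_subjects_rejected(self, small_cohort):
        _, dataset, _ = small_cohort
        few = dataset.records[
            dataset.records["subject_id"].isin(dataset.subjects.index[:4])
        ]
        with pytest.raises(ValueError):
            fit_lclmm(few, LCLMMSpec(n_classes=3))


class TestPosteriors:
    def test_rows_sum_to_one_and_single_class_certain(self, small_cohort):
        _, dataset, _ = small_cohort
        spec = LCLMMSpec(n_classes=1)
        fit = fit_lclmm(dataset, spec, n_starts=1, tol=1e-6, max_iter=200)
        assert np.allclose(fit.posterior.to_numpy(), 1.0)
        spec3 = LCLMMSpec(n_classes=3)
        fit3 = fit_lclmm(dataset, spec3, n_starts=2, tol=1e-6, max_iter=200, seed=0)
        sums = fit3.posterior.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-10)

    def test_average_posterior_diagonal_dominant(self, small_cohort):
        _, dataset, _ = small_cohort
        spec = LCLMMSpec(n_classes=3)
        fit = fit_lclmm(dataset, spec, n_starts=4, tol=1e-6, max_iter=400, seed=0)
        diag = np.diag(fit.average_posterior_table().to_numpy())
        assert np.all(diag > 0.5)  # each modal class owns its members on average

    def test_posterior_probs_on_external_params(self, tiny_design, tiny_params):
        design, spec = tiny_design
        posterior, assignment, avg = posterior_probs(tiny_params, design, spec)
        assert posterior.shape == (design.n_subjects, 1)
        assert (assignment == 1).all()


class TestSelectNumClasses:
    def test_min_share_disqualifies(self, small_cohort):
        _, dataset, _ = small_cohort
        # a 50% minimum share cannot be met by any multi-class fit here
        selected, fits, report = select_num_classes(
            dataset,
            LCLMMSpec(n_classes=1),
            G_range=(1, 2),
            min_share=0.5,
            n_starts=2,
            tol=1e-6,
            max_iter=150,
            seed=0,
        )
        assert selected == 1
        assert not report.loc[2, "qualified"]
        assert "share" in report.loc[2, "reason"]

    def test_single_class_data_selects_one(self, single_class_cohort):
        _, dataset, _ = single_class_cohort
        selected, _, _ = select_num_classes(
            dataset,
            LCLMMSpec(n_classes=1),
            G_range=(1, 2),
            min_share=0.02,
            n_starts=2,
            tol=1e-6,
            max_iter=200,
            seed=0,
        )
        assert selected == 1

    def test_empty_range_rejected(self, small_cohort):
        _, dataset, _ = small_cohort
        with pytest.raises(ValueError):
            select_num_classes(dataset, LCLMMSpec(n_classes=1), G_range=())
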