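"""Hierarchical-model internals: gradients, R-hat, exclusions, sampler."""

import numpy as np
import pytest

from cuetd._kernels import loglik_grad_fast, loglik_grad_numpy
from cuetd._nuts import sample_nuts
from cuetd.inference import (
    PriorSpec,
    SamplerConfig,
    _HierarchicalPosterior,
    compute_rhat,
    exclude_degenerate_subjects,
    stack_datasets,
)
from cuetd.models import ModelVariant
from cuetd.simulate import GroundTruth, simulate_cohort
from cuetd.task import ChoiceDataset, build_design


class TestLoglikKernels:
    @pytest.mark.parametrize("has_offset", [True, False])
    @pytest.mark.parametrize("has_shifts", [True, False])
    def test_fast_kernel_matches_reference(self, small_cohort, rng,
                                           has_offset, has_shifts):
        datasets, _ = small_cohort
        data = stack_datasets(datasets)
        val = rng.normal(scale=0.8, size=(6, data.n_subjects))
        args = (val, data.ll_amount, data.delay, data.i_ero, data.sign,
                data.ss_amount, data.subj, has_offset, has_shifts)
        l_ref, g_ref = loglik_grad_numpy(*args)
        l_fast, g_fast = loglik_grad_fast(*args)
        assert l_fast == pytest.approx(l_ref, rel=1e-12)
        np.testing.assert_allclose(g_fast, g_ref, rtol=1e-9, atol=1e-12)


class TestPosteriorGradient:
    @pytest.mark.parametrize("variant", ["base", "offset"])
    def test_analytic_gradient_matches_finite_differences(self, small_cohort,
                                                          rng, variant):
        datasets, _ = small_cohort
        data = stack_datasets(datasets)
        post = _HierarchicalPosterior(data, ModelVariant(variant), PriorSpec())
        q = post.initial_point(rng)
        _, grad = post.logp_and_grad(q)
        eps = 1e-6
        for i in rng.choice(q.size, size=20, replace=False):
            qp, qm = q.copy(), q.copy()
            qp[i] += eps
            qm[i] -= eps
            fd = (post.logp_and_grad(qp)[0] - post.logp_and_grad(qm)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-5)

    def test_single_condition_drops_shift_families(self, design_set1):
        rng = np.random.default_rng(0)
        datasets = []
        for s in range(3):
            choices = ["SS" if rng.random() < 0.4 else "LL" for _ in range(128)]
            datasets.append(ChoiceDataset(f"s{s}", design_set1, choices,
                                          "neutral"))
        data = stack_datasets(datasets)
        post = _HierarchicalPosterior(data, ModelVariant("offset"), PriorSpec())
        assert "s_ero_k" not in post.families
        assert post.F == 3  # log k, beta, logit omega


class TestNutsSampler:
    def test_recovers_correlated_gaussian(self):
        """On a known 3-d Gaussian target the sampler must reproduce the
        mean and covariance diagonal."""
        cov = np.array([[1.0, 0.5, 0.0], [0.5, 2.0, 0.3], [0.0, 0.3, 0.5]])
        prec = np.linalg.inv(cov)
        mean = np.array([1.0, -2.0, 0.5])

        def logp_and_grad(q):
            d = q - mean
            return -0.5 * d @ prec @ d, -prec @ d

        rng = np.random.default_rng(4)
        draws, stats = sample_nuts(logp_and_grad, np.zeros(3), 500, 2000, rng)
        assert stats.n_divergent == 0
        np.testing.assert_allclose(draws.mean(axis=0), mean, atol=0.1)
        np.testing.assert_allclose(draws.var(axis=0), np.diag(cov), rtol=0.15)

    def test_deterministic_given_seed(self):
        def logp_and_grad(q):
            return -0.5 * q @ q, -q

        out = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            draws, _ = sample_nuts(logp_and_grad, np.zeros(2), 100, 50, rng)
            out.append(draws)
        np.testing.assert_array_equal(out[0], out[1])


class TestRhat:
    def test_same_distribution_near_one(self, rng):
        params = {"a": rng.standard_normal((4, 2000))}
        report = compute_rhat(params)
        assert report.rhat["a"] < 1.01
        assert report.passed

    def test_offset_chains_fail(self, rng):
        x = rng.standard_normal((2, 500))
        x[1] += 10.0
        report = compute_rhat({"a": x})
        assert report.rhat["a"] > 1.05
        assert not report.passed

    def test_constant_chains_flagged_not_failed(self, rng):
        report = compute_rhat({"a": np.full((2, 100), 2.5),
                               "b": rng.standard_normal((2, 100))})
        assert report.rhat["a"] == 1.0
        assert "a" in report.zero_variance

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_rhat({"a": rng.standard_normal((1, 100))})


class TestExclusion:
    def _cohort(self, ss_counts):
        """One dataset per condition per subject with given total SS counts."""
        design = build_design(1, 20.0)
        datasets = []
        for s, n_ss in enumerate(ss_counts):
            per = [n_ss - n_ss // 2, n_ss // 2]
            for cond, n in zip(("neutral", "erotic"), per):
                choices = ["SS"] * n + ["LL"] * (128 - n)
                datasets.append(ChoiceDataset(f"s{s}", design, choices, cond))
        return datasets

    def test_single_minority_choice_excluded(self):
        kept, excluded = exclude_degenerate_subjects(self._cohort([1, 40]), 2)
        assert excluded == ["s0"]
        assert {d.subject_id for d in kept} == {"s1"}

    def test_boundary_kept(self):
        kept, excluded = exclude_degenerate_subjects(self._cohort([2, 40]), 2)
        assert excluded == []

    def test_threshold_zero_keeps_all(self):
        kept, excluded = exclude_degenerate_subjects(self._cohort([0, 0]), 0)
        assert excluded == []

    def test_all_excluded_is_error(self):
        with pytest.raises(ValueError, match="all subjects"):
            exclude_degenerate_subjects(self._cohort([0, 1]), 2)

    def test_minority_side_is_symmetric(self):
        # all-SS subject is just as degenerate as all-LL
        kept, excluded = exclude_degenerate_subjects(self._cohort([255, 40]), 2)
        assert excluded == ["s0"]


class TestSmallFits:
    """Cheap end-to-end fits probing structural behaviour of fit_model."""

    def test_single_condition_fit_pins_shifts_at_zero(self, design_set1):
        from cuetd.inference import fit_model

        rng = np.random.default_rng(1)
        datasets = [
            ChoiceDataset(f"s{s}",
                          design_set1,
                          ["SS" if rng.random() < 0.4 else "LL"
                           for _ in range(128)],
                          "neutral")
            for s in range(3)
        ]
        config = SamplerConfig(n_chains=2, n_warmup=120, n_retained=120,
                               seed=4)
        posterior, report = fit_model(datasets, "offset", config=config)
        for name in ("mu_s_ero_k", "mu_s_ero_beta", "mu_s_ero_logit_omega"):
            assert np.all(posterior.params[name] == 0.0)
            assert name in report.zero_variance

    def test_near_empty_data_posterior_matches_prior(self):
        """With almost no trials the group-mean posteriors must stay close
        to their priors (prior-predictive sanity)."""
        from cuetd.inference import fit_model
        from cuetd.task import Trial

        trials = [Trial(20.2, 1, 0, 0)]  # one near-indifferent trial
        datasets = [ChoiceDataset(f"s{s}", trials, ["SS"], "neutral")
                    for s in range(2)]
        config = SamplerConfig(n_chains=2, n_warmup=300, n_retained=2000,
                               seed=8)
        posterior, _ = fit_model(datasets, "base", config=config)
        priors = PriorSpec()
        for name, (m, sd) in [("mu_log_k_neut", priors.log_k),
                              ("mu_beta_neut", priors.beta)]:
            x = posterior.stacked(name)
            assert x.mean() == pytest.approx(m, abs=0.5 * sd)
            assert x.std() == pytest.approx(sd, rel=0.35)


class TestSamplerConfigDefaults:
    def test_study_scale_defaults(self):
        c = SamplerConfig()
        assert (c.n_chains, c.n_warmup, c.n_retained) == (4, 1500, 4000)
        assert c.rhat_threshold == 1.05
        assert c.draws_per_chain == 1000

    def test_reduced_config(self):
        c = SamplerConfig.reduced(seed=9)
        assert (c.n_chains, c.n_warmup, c.draws_per_chain) == (2, 400, 400)

    def test_prior_defaults(self):
        p = PriorSpec()
        assert p.log_k == (-4.2, 2.01)
        assert p.s_ero_k == (0.15, 0.64)
        assert p.beta == (0.51, 0.3)
        assert p.s_ero_beta == (0.02, 0.11)
        assert p.omega == (0.0, 1.0)
        assert p.s_ero_omega == (0.0, 0.4)
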