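"""EM / Newton estimation, standard errors, posteriors, diagnostics."""

import numpy as np
import pytest

from mixirt.estimate import (
    FitConfig,
    FitResult,
    ParamBlocks,
    compute_standard_errors,
    diagnose_solution,
    fit_em,
    loglik_and_score,
    multi_start_fit,
    n_free_parameters,
    pack_parameters,
    posterior_classification,
    random_start,
    refine_newton,
    unpack_parameters,
)
from mixirt.model import ModelSpec, ParameterSet, build_quadrature
from mixirt.selection import count_free_parameters
from mixirt.simulate import generate_dataset

PURE_ML = dict(prior_strength=0.0)


def test_pack_unpack_round_trip(small_params, small_spec):
    theta = pack_parameters(small_params, small_spec)
    assert theta.size == n_free_parameters(small_spec)
    back = unpack_parameters(theta, small_spec)
    np.testing.assert_array_equal(back.delta_beta, small_params.delta_beta)
    np.testing.assert_array_equal(back.item_discrimination,
                                  small_params.item_discrimination)


def test_free_parameter_count_matches_enumeration():
    """Cross-module: the optimized vector length equals the IC count."""
    for spec in (ModelSpec(5, 11, 3), ModelSpec(5, 11, 3, True),
                 ModelSpec(2, 4, 2), ModelSpec(1, 2, 1, True)):
        assert n_free_parameters(spec) == count_free_parameters(spec)


@pytest.mark.parametrize("prior", [0.0, 1.0])
def test_analytic_score_matches_numerical_gradient(small_params, small_spec,
                                                   prior):
    rng = np.random.default_rng(0)
    x = rng.integers(0, 4, size=(25, 2))
    grid = build_quadrature(30)
    theta = pack_parameters(small_params, small_spec)
    _, grad = loglik_and_score(theta, x, small_spec, grid,
                               prior_strength=prior)
    h = 1e-6
    for k in range(0, theta.size, 3):
        hi, lo = theta.copy(), theta.copy()
        hi[k] += h
        lo[k] -= h
        num = (loglik_and_score(hi, x, small_spec, grid,
                                prior_strength=prior)[0]
               - loglik_and_score(lo, x, small_spec, grid,
                                  prior_strength=prior)[0]) / (2 * h)
        assert grad[k] == pytest.approx(num, abs=1e-5, rel=1e-5)


class TestFitEm:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_monotone_nondecreasing(self, small_params, small_spec,
                                              seed):
        rng = np.random.default_rng(seed)
        data = generate_dataset(small_params, 300, seed=seed)
        start = random_start(small_spec, rng)
        fit = fit_em(data.responses, small_spec, start,
                     FitConfig(n_quadrature=30), max_iter=60)
        diffs = np.diff(fit.loglik_path)
        assert (diffs >= -1e-8).all()

    def test_one_class_pcm_recovery_at_large_n(self):
        """Parameter-recovery oracle: 1-class PCM, max error over all 50
        step parameters below 0.08 at large N.

        Uniform generating steps keep every category populated; N = 50,000
        puts the per-coordinate sampling SD near 0.026, so the worst of 50
        coordinates stays inside the band with room to spare.
        """
        truth = ParameterSet(np.zeros((1, 5, 10)), np.ones(5), [0.4], [0.0])
        spec = ModelSpec(5, 11, 1, equal_discrimination=True)
        data = generate_dataset(truth, 50_000, seed=8)
        start = truth.copy()
        start.delta_beta = np.full_like(start.delta_beta, 0.3)
        fit = fit_em(data.responses, spec, start,
                     FitConfig(n_quadrature=40, em_tol=1e-4, **PURE_ML))
        assert np.abs(fit.params.delta_beta - truth.delta_beta).max() < 0.08

    def test_incompatible_start_rejected(self, small_params):
        with pytest.raises(ValueError):
            fit_em(np.zeros((5, 2), dtype=int), ModelSpec(2, 4, 3),
                   small_params, FitConfig(n_quadrature=10))


class TestRefineNewton:
    def _converged_fit(self, seed=0):
        rng = np.random.default_rng(seed)
        truth = ParameterSet(rng.uniform(-1, 1, (1, 2, 2)), np.ones(2),
                             [0.5], [0.0])
        spec = ModelSpec(2, 3, 1, equal_discrimination=True)
        data = generate_dataset(truth, 400, seed=seed)
        cfg = FitConfig(n_quadrature=30, **PURE_ML)
        fit = fit_em(data.responses, spec, truth, cfg)
        return fit, data, cfg, spec

    def test_toy_model_reaches_small_gradient(self):
        fit, data, cfg, spec = self._converged_fit()
        refined = refine_newton(fit, data.responses, cfg)
        grid = cfg.grid()
        _, grad = loglik_and_score(
            pack_parameters(refined.params, spec), data.responses, spec, grid)
        assert np.abs(grad).max() < 1e-6
        assert refined.nr_converged

    def test_stationary_input_returned_quickly(self):
        fit, data, cfg, _ = self._converged_fit(1)
        refined = refine_newton(fit, data.responses, cfg)
        again = refine_newton(refined, data.responses, cfg)
        assert again.nr_iterations <= 3
        assert again.objective == pytest.approx(refined.objective, abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_never_decreases_objective(self, small_params, small_spec, seed):
        data = generate_dataset(small_params, 120, seed=seed)
        cfg = FitConfig(n_quadrature=20, nr_max_iter=40)
        start = random_start(small_spec, np.random.default_rng(seed))
        fit = fit_em(data.responses, small_spec, start, cfg, max_iter=15)
        refined = refine_newton(fit, data.responses, cfg)
        assert refined.objective >= fit.objective - 1e-8
        assert refined.loglik_path is fit.loglik_path


class TestMultiStart:
    def test_single_start_equals_em_then_newton(self, small_params,
                                                small_spec):
        data = generate_dataset(small_params, 200, seed=3)
        cfg = FitConfig(n_quadrature=20, n_starts=1, start_em_iter=30,
                        warm_start=small_params, nr_max_iter=50)
        best = multi_start_fit(data.responses, small_spec, cfg, seed=0)
        short = fit_em(data.responses, small_spec, small_params, cfg,
                       max_iter=30)
        manual = fit_em(data.responses, small_spec, short.params, cfg)
        manual = refine_newton(manual, data.responses, cfg)
        assert best.objective >= short.objective - 1e-8
        assert best.objective == pytest.approx(manual.objective, abs=1e-6)

    def test_deterministic_given_seed(self, small_params, small_spec):
        data = generate_dataset(small_params, 150, seed=4)
        cfg = FitConfig(n_quadrature=20, n_starts=3, start_em_iter=10,
                        nr_max_iter=30)
        a = multi_start_fit(data.responses, small_spec, cfg, seed=5)
        b = multi_start_fit(data.responses, small_spec, cfg, seed=5)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.params.delta_beta, b.params.delta_beta)

    def test_replicated_optimum_on_separated_mixture(self):
        """Well-separated 2-class mixture: seeded runs agree on the optimum."""
        delta = np.stack([np.full((2, 3), 1.5), np.full((2, 3), -1.5)])
        truth = ParameterSet(delta, np.ones(2), [0.4, 0.4], [0.0, 0.0])
        spec = ModelSpec(2, 4, 2, equal_discrimination=True)
        data = generate_dataset(truth, 600, seed=11)
        cfg = FitConfig(n_quadrature=20, n_starts=25, start_em_iter=100,
                        em_tol=1e-4, nr_max_iter=300)
        logliks = [multi_start_fit(data.responses, spec, cfg, seed=s).objective
                   for s in range(5)]
        best = max(logliks)
        assert sum(best - ll < 0.01 for ll in logliks) >= 5


class TestStandardErrors:
    def test_binomial_closed_form(self):
        """1-class, 1-item, 2-category: SE matches the logit formula."""
        n = 4000
        truth = ParameterSet(np.full((1, 1, 1), 0.4), [1.0], [1e-4], [0.0])
        spec = ModelSpec(1, 2, 1, equal_discrimination=True)
        data = generate_dataset(truth, n, seed=12)
        cfg = FitConfig(n_quadrature=10, **PURE_ML)
        fit = fit_em(data.responses, spec, truth, cfg)
        fit = refine_newton(fit, data.responses, cfg)
        fit = compute_standard_errors(fit, data.responses, cfg)
        p = data.responses.mean()
        closed = np.sqrt(1.0 / (n * p * (1 - p)))
        assert fit.standard_errors.delta_beta[0, 0, 0] == pytest.approx(
            closed, rel=0.02)

    def test_root_n_scaling(self):
        truth = ParameterSet(np.array([[[-0.5, 0.2, 0.6],
                                        [0.4, -0.3, 0.1]]]),
                             np.ones(2), [0.5], [0.0])
        spec = ModelSpec(2, 4, 1, equal_discrimination=True)
        cfg = FitConfig(n_quadrature=20, **PURE_ML)
        ses = []
        for n in (800, 3200):
            data = generate_dataset(truth, n, seed=13)
            fit = fit_em(data.responses, spec, truth, cfg)
            fit = compute_standard_errors(fit, data.responses, cfg)
            ses.append(np.nanmedian(fit.standard_errors.delta_beta))
        assert 1.8 <= ses[0] / ses[1] <= 2.2

    def test_degenerate_flat_data_flags_boundaries(self):
        spec = ModelSpec(2, 3, 1, equal_discrimination=True)
        truth = ParameterSet(np.zeros((1, 2, 2)), np.ones(2), [0.5], [0.0])
        x = np.zeros((80, 2), dtype=int)  # every response identical
        cfg = FitConfig(n_quadrature=10, em_max_iter=3000, em_tol=1e-12,
                        **PURE_ML)
        fit = fit_em(x, spec, truth, cfg)
        fit = compute_standard_errors(fit, x, cfg)
        assert fit.se_boundary.delta_beta.sum() > 0

    def test_opg_close_to_observed_information(self):
        """At a stationary point of a well-specified 1-class model the OPG
        and observed-information SEs agree asymptotically."""
        truth = ParameterSet(np.array([[[-0.5, 0.2, 0.6],
                                        [0.4, -0.3, 0.1]]]),
                             np.ones(2), [0.5], [0.0])
        spec = ModelSpec(2, 4, 1, equal_discrimination=True)
        data = generate_dataset(truth, 2000, seed=14)
        cfg = FitConfig(n_quadrature=20, em_tol=1e-6, **PURE_ML)
        fit = fit_em(data.responses, spec, truth, cfg)
        fit = refine_newton(fit, data.responses, cfg)
        obs = compute_standard_errors(fit, data.responses, cfg)
        se_obs = obs.standard_errors.delta_beta.copy()
        opg = compute_standard_errors(
            fit, data.responses, FitConfig(n_quadrature=20, se_method="opg",
                                           **PURE_ML))
        ratio = opg.standard_errors.delta_beta / se_obs
        assert np.nanmedian(ratio) == pytest.approx(1.0, abs=0.25)


class TestPosteriorClassification:
    def test_single_class_posterior_is_one(self, small_params):
        truth = ParameterSet(small_params.delta_beta[:1], [1.0, 1.3],
                             [0.5], [0.0])
        spec = ModelSpec(2, 4, 1)
        data = generate_dataset(truth, 50, seed=15)
        fit = fit_em(data.responses, spec, truth,
                     FitConfig(n_quadrature=10), max_iter=3)
        fit = posterior_classification(fit, data.responses,
                                       FitConfig(n_quadrature=10))
        np.testing.assert_allclose(fit.posterior, 1.0)
        assert fit.mean_assignment_probability == 1.0

    def test_identical_classes_give_prior_proportions(self):
        delta = np.tile(np.array([[0.3, -0.2, 0.5]]), (2, 1, 1))
        params = ParameterSet(delta.reshape(2, 1, 3), [1.0], [0.4, 0.4],
                              [0.0, 0.8])
        spec = ModelSpec(1, 4, 2, equal_discrimination=True)
        data = generate_dataset(params, 40, seed=16)
        fit = FitResult(spec=spec, params=params, loglik=0.0, objective=0.0,
                        n_free_parameters=5, em_converged=True,
                        em_iterations=0)
        fit = posterior_classification(fit, data.responses,
                                       FitConfig(n_quadrature=20))
        from mixirt.model import class_proportions
        pi = class_proportions(params.class_logit)
        np.testing.assert_allclose(fit.posterior,
                                   np.tile(pi, (40, 1)), atol=1e-10)

    def test_enumeration_oracle_two_items(self, small_spec, small_params):
        """Posteriors match brute-force summation over the response pattern."""
        data = generate_dataset(small_params, 30, seed=17)
        cfg = FitConfig(n_quadrature=40)
        fit = fit_em(data.responses, small_spec, small_params, cfg,
                     max_iter=2)
        fit = posterior_classification(fit, data.responses, cfg)
        grid = cfg.grid()
        from mixirt.model import category_probabilities, class_proportions
        pi = class_proportions(fit.params.class_logit)
        for v in range(5):
            num = np.zeros(2)
            for g in range(2):
                like = 0.0
                for q, w in zip(grid.nodes, grid.weights):
                    term = w
                    for i in range(2):
                        term *= category_probabilities(
                            fit.params, g, i, q)[data.responses[v, i]]
                    like += term
                num[g] = pi[g] * like
            np.testing.assert_allclose(fit.posterior[v], num / num.sum(),
                                       atol=1e-10)


class TestDiagnoseSolution:
    def _fit_with_flags(self, n_flagged):
        spec = ModelSpec(5, 11, 3)
        shape = (3, 5, 10)
        flags = np.zeros(150)
        flags[:n_flagged] = 1.0
        blocks = ParamBlocks(flags.reshape(shape),
                             np.zeros(5), np.zeros(3), np.zeros(3))
        params = ParameterSet(np.zeros(shape), np.ones(5),
                              np.full(3, 0.2), np.zeros(3))
        return FitResult(spec=spec, params=params, loglik=-1.0,
                         objective=-1.0, n_free_parameters=159,
                         em_converged=True, em_iterations=1,
                         se_boundary=blocks)

    def test_ten_percent_rule_is_strict(self):
        # 159 free parameters: 16/159 = 10.06% > 10% -> improper
        improper, summary = diagnose_solution(self._fit_with_flags(16))
        assert improper
        improper, _ = diagnose_solution(self._fit_with_flags(15))
        assert not improper  # 15/159 = 9.4%
        improper, _ = diagnose_solution(self._fit_with_flags(0))
        assert not improper

    def test_requires_standard_errors(self, small_params, small_spec):
        fit = FitResult(spec=small_spec, params=small_params, loglik=0.0,
                        objective=0.0, n_free_parameters=1,
                        em_converged=True, em_iterations=1)
        with pytest.raises(ValueError):
            diagnose_solution(fit)


def test_label_permutation_equivariance(small_params, small_spec):
    """Permuting the start's class labels permutes the solution."""
    data = generate_dataset(small_params, 250, seed=18)
    cfg = FitConfig(n_quadrature=20)
    fit = fit_em(data.responses, small_spec, small_params, cfg, max_iter=25)
    swapped_start = small_params.permute_classes([1, 0])
    fit_swapped = fit_em(data.responses, small_spec, swapped_start, cfg,
                         max_iter=25)
    np.testing.assert_allclose(
        fit_swapped.params.delta_beta,
        fit.params.permute_classes([1, 0]).delta_beta, atol=1e-8)
    assert fit_swapped.loglik == pytest.approx(fit.loglik, abs=1e-8)
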