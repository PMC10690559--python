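import math

import numpy as np
import pytest
from scipy.integrate import quad

from ctdnakin.kinetics.models import one_step, three_step, two_step
from ctdnakin.population import (
    DEFAULT_BETA_BOUNDS,
    FitConfig,
    _BatchedCohort,
    _PatientArrays,
    _pack_bounds,
    build_effect_structure,
    compose_effects,
    conditional_mode,
    extract_random_effects,
    fit_population,
    gauss_newton_mode,
    laplace_marginal,
    link,
    marginal_loglik_foce,
    patient_loglik,
)

_LOG2PI = math.log(2 * math.pi)


class TestEffectStructure:
    @pytest.mark.parametrize(
        "model,n_beta,n_random,n_pop",
        [(one_step(), 2, 2, 5), (two_step(), 4, 3, 8), (three_step(), 6, 5, 12)],
        ids=["one_step", "two_step", "three_step"],
    )
    def test_counts(self, model, n_beta, n_random, n_pop):
        s = build_effect_structure(model)
        assert s.n_beta == n_beta
        assert s.n_random == n_random
        assert s.n_population == n_pop

    def test_three_step_partition(self):
        s = build_effect_structure(three_step())
        assert s.random_names == ("B0", "c0pb", "gamma_d", "s_c", "alpha")
        assert s.beta_names[-1] == "gamma_t"

    def test_one_step_has_no_shared_rate(self):
        s = build_effect_structure(one_step())
        assert "gamma_t" not in s.beta_names


class TestComposeEffects:
    def test_zero_random_effects_give_typical_values(self, three_step_structure):
        beta = np.array([math.log(5e11), math.log(1e9), math.log(0.5),
                         math.log(1.0), math.log(1e-3), math.log(2.0)])
        e = compose_effects(three_step_structure, beta)
        assert e.B0 == pytest.approx(5e11)
        assert e.s_c == pytest.approx(2.0)     # 1 + exp
        assert e.alpha == pytest.approx(1e-3)

    def test_links_enforce_ranges(self, three_step_structure):
        rng = np.random.default_rng(0)
        for _ in range(50):
            beta = rng.normal(-1, 2, size=6)
            beta[4] = -abs(beta[4])  # alpha <= 1
            b = rng.normal(0, 1, size=5)
            b[4] = -abs(b[4])
            e = compose_effects(three_step_structure, beta, b)
            assert e.s_c >= 1.0
            assert 0 < e.alpha <= 1.0
            assert min(e.B0, e.c0pb, e.gamma_d, e.gamma_t) > 0

    def test_round_trip_recovers_b(self, three_step_structure):
        rng = np.random.default_rng(1)
        beta = rng.normal(0, 1, size=6)
        beta[4] = -1.5
        b = rng.normal(0, 0.5, size=5)
        e = compose_effects(three_step_structure, beta, b)
        b_back = extract_random_effects(three_step_structure, beta, e)
        assert np.allclose(b_back, b, atol=1e-12)

    def test_length_mismatch_rejected(self, three_step_structure):
        with pytest.raises(ValueError, match="shape"):
            compose_effects(three_step_structure, np.zeros(3))


class TestPatientLoglik:
    def test_zero_residual_value(self, small_cohort):
        truth, prep = small_cohort
        p = prep[0]
        effects = truth.effects_of(p.patient_id)
        # build a patient whose observations equal the model outputs exactly
        from ctdnakin.kinetics.solutions import solve_analytic
        from dataclasses import replace

        traj_b = solve_analytic(truth.structure.model, effects, p.blast_times)
        traj_c = solve_analytic(truth.structure.model, effects, p.ctdna_times)
        exact = replace(
            p,
            blast_counts=traj_b.observable("y_blast"),
            ctdna_counts=traj_c.observable("y_ctdna"),
        )
        sigma = 0.2
        ll = patient_loglik(exact, effects, sigma, structure=truth.structure)
        m_c, m_b = len(p.ctdna_times), len(p.blast_times)
        expected = (
            -m_c * (0.5 * _LOG2PI + math.log(sigma))
            - m_b * 0.5 * _LOG2PI
            - float(np.sum(np.log(exact.blast_sds)))
        )
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_matches_independent_density_sum(self, small_cohort):
        truth, prep = small_cohort
        p = prep[1]
        effects = truth.effects_of(p.patient_id)
        sigma = 0.15
        ll = patient_loglik(p, effects, sigma, structure=truth.structure)
        # independent recomputation with scipy.stats
        from scipy.stats import norm
        from ctdnakin.kinetics.solutions import solve_analytic

        model = truth.structure.model
        yb = solve_analytic(model, effects, p.blast_times).observable("y_blast")
        yc = solve_analytic(model, effects, p.ctdna_times).observable("y_ctdna")
        expected = float(
            np.sum(norm.logpdf(p.blast_counts, loc=yb, scale=p.blast_sds))
            + np.sum(norm.logpdf(np.log10(p.ctdna_counts), loc=np.log10(yc), scale=sigma))
        )
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_doubling_residual_decreases_loglik(self, small_cohort):
        truth, prep = small_cohort
        from dataclasses import replace

        p = prep[2]
        effects = truth.effects_of(p.patient_id)
        ll0 = patient_loglik(p, effects, 0.1, structure=truth.structure)
        worse = replace(p, ctdna_counts=p.ctdna_counts * 4.0)
        ll1 = patient_loglik(worse, effects, 0.1, structure=truth.structure)
        assert ll1 < ll0


class TestConditionalModeToys:
    def _linear_toy(self, beta, y, se2):
        def res(b):
            r = np.array([(beta + b[0] - y) / math.sqrt(se2)])
            J = np.array([[1.0 / math.sqrt(se2)]])
            return r, J, -0.5 * _LOG2PI - 0.5 * math.log(se2)

        return res

    def test_conjugate_closed_form(self):
        beta, y, sb2, se2 = 1.0, 2.3, 0.7, 0.4
        fit = gauss_newton_mode(self._linear_toy(beta, y, se2), np.array([sb2]))
        assert fit.b_hat[0] == pytest.approx(sb2 / (sb2 + se2) * (y - beta), rel=1e-8)
        assert fit.converged

    def test_vanishing_prior_pins_b_at_zero(self):
        fit = gauss_newton_mode(self._linear_toy(1.0, 5.0, 0.4), np.array([1e-12]))
        assert abs(fit.b_hat[0]) < 1e-10

    def test_vanishing_noise_pins_b_at_data(self):
        fit = gauss_newton_mode(self._linear_toy(1.0, 5.0, 1e-12), np.array([0.7]))
        assert fit.b_hat[0] == pytest.approx(4.0, rel=1e-6)


class TestLaplace:
    def test_exact_on_linear_gaussian(self):
        beta, y, sb2, se2 = 0.3, 1.9, 0.5, 0.2

        def res(b):
            r = np.array([(beta + b[0] - y) / math.sqrt(se2)])
            J = np.array([[1.0 / math.sqrt(se2)]])
            return r, J, -0.5 * _LOG2PI - 0.5 * math.log(se2)

        ll, _ = laplace_marginal(res, np.array([sb2]))
        exact = -0.5 * math.log(2 * math.pi * (sb2 + se2)) - 0.5 * (y - beta) ** 2 / (sb2 + se2)
        assert ll == pytest.approx(exact, abs=1e-12)

    def test_within_one_percent_of_quadrature(self):
        """Nonlinear 1-D toys across 20 seeded configurations."""
        rng = np.random.default_rng(11)
        m = 5
        for _ in range(20):
            beta = rng.normal(0, 0.5)
            sb2 = rng.uniform(0.05, 0.3)
            se = rng.uniform(0.02, 0.08)
            b_true = rng.normal(0, math.sqrt(sb2))
            ys = np.exp(beta + b_true) + rng.normal(0, se, m)

            def res(b):
                mu = math.exp(beta + b[0])
                return (
                    (mu - ys) / se,
                    np.full((m, 1), mu / se),
                    m * (-0.5 * _LOG2PI - math.log(se)),
                )

            ll, fit = laplace_marginal(res, np.array([sb2]))

            def integrand(b):
                mu = math.exp(beta + b)
                return math.exp(-0.5 * float(np.sum((mu - ys) ** 2)) / se**2 - 0.5 * b * b / sb2)

            # hint the quadrature at the (narrow) posterior mode
            q, _ = quad(
                integrand, -8 * math.sqrt(sb2), 8 * math.sqrt(sb2),
                points=[float(fit.b_hat[0])], limit=300,
            )
            logq = (
                math.log(q)
                + m * (-0.5 * _LOG2PI - math.log(se))
                - 0.5 * math.log(2 * math.pi * sb2)
            )
            assert abs(ll - logq) <= 0.01 * abs(logq)

    def test_additivity_over_patients(self, small_cohort):
        truth, prep = small_cohort
        s = truth.structure
        ll_all = marginal_loglik_foce(prep, s, truth.beta, truth.delta, 0.1)
        ll_parts = sum(
            marginal_loglik_foce([p], s, truth.beta, truth.delta, 0.1) for p in prep
        )
        assert ll_all == pytest.approx(ll_parts, rel=1e-12)


class TestConditionalModeKinetic:
    def test_batched_matches_sequential(self, small_cohort):
        truth, prep = small_cohort
        s = truth.structure
        arrays = [_PatientArrays.from_patient(p) for p in prep]
        batch = _BatchedCohort(s, arrays, "log10")
        seq = marginal_loglik_foce(prep, s, truth.beta, truth.delta, 0.1)
        val, _ = batch.neg_marginal(truth.beta, truth.delta, 0.1)
        assert -val == pytest.approx(seq, rel=1e-9)

    def test_warm_start_consistency(self, small_cohort):
        truth, prep = small_cohort
        s = truth.structure
        fit0 = conditional_mode(prep[0], s, truth.beta, truth.delta, 0.1)
        fit1 = conditional_mode(prep[0], s, truth.beta, truth.delta, 0.1, b0=fit0.b_hat)
        assert np.allclose(fit0.b_hat, fit1.b_hat, atol=1e-6)

    def test_observable_subset_validation(self, small_cohort):
        truth, prep = small_cohort
        with pytest.raises(ValueError, match="observable"):
            conditional_mode(
                prep[0], truth.structure, truth.beta, truth.delta, 0.1,
                use_blasts=False, use_ctdna=False,
            )


class TestFitPopulation:
    def test_objective_finite_at_lhs_starts(self, small_cohort):
        truth, prep = small_cohort
        s = truth.structure
        config = FitConfig(n_starts=20, seed=3)
        bounds = _pack_bounds(s, config)
        from scipy.stats import qmc

        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        pts = lo + qmc.LatinHypercube(d=lo.size, seed=3).random(20) * (hi - lo)
        arrays = [_PatientArrays.from_patient(p) for p in prep]
        batch = _BatchedCohort(s, arrays, "log10")
        for x in pts:
            val, _ = batch.neg_marginal(x[:6], x[6:11], math.exp(x[-1]))
            assert np.isfinite(val)

    def test_deterministic_given_seed(self, small_cohort):
        truth, prep = small_cohort
        config = FitConfig(n_starts=2, seed=9, maxiter=200)
        a = fit_population(prep, truth.structure, config)
        b = fit_population(prep, truth.structure, config)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.delta, b.delta)
        assert a.sigma_c == b.sigma_c
        assert a.loglik == b.loglik

    def test_waterfall_sorted_and_table_complete(self, small_cohort):
        truth, prep = small_cohort
        est = fit_population(prep, truth.structure, FitConfig(n_starts=3, seed=1, maxiter=200))
        wf = est.waterfall()
        assert np.all(np.diff(wf) <= 0)
        assert len(est.multistart_table) == 3
        assert est.structure.n_population == 12

    def test_needs_two_patients(self, small_cohort):
        truth, prep = small_cohort
        with pytest.raises(ValueError, match="2 patients"):
            fit_population(prep[:1], truth.structure, FitConfig(n_starts=1))

    def test_estimate_serialization(self, small_cohort):
        truth, prep = small_cohort
        est = fit_population(prep, truth.structure, FitConfig(n_starts=2, seed=1, maxiter=200))
        d = est.to_dict()
        assert len(d["beta_transformed"]) == 6
        assert len(d["delta_log_variance"]) == 5
        assert d["n_population_parameters"] == 12
        assert set(d["typical_values_natural"]) == set(est.structure.beta_names)


class TestLinks:
    def test_link_inverse(self):
        assert link("B0", 5e11) == pytest.approx(math.log(5e11))
        assert link("s_c", 2.0) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            link("s_c", 0.9)
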