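import numpy as np
import pytest

import naive_ref
from conftest import random_params
from revlearn import (AgentParams, Session, TaskConfig, fit_both, fit_model,
                      generate_cohort, group_and_individual_fits,
                      information_criteria, likelihood_ratio_test,
                      negative_log_likelihood, simulate_session)
from revlearn.fitting import FitResult


def _make_fit(model, L, k, N):
    aic, bic = information_criteria(L, k, N)
    return FitResult(model=model, params=AgentParams(0.1, 1.0, 0.0),
                     log_likelihood=L, aic=aic, bic=bic, n_params=k,
                     n_obs=N, converged=True, n_restarts=1)


class TestNegativeLogLikelihood:
    def test_zero_beta_gives_uniform_likelihood(self, hybrid_session):
        nll = negative_log_likelihood(AgentParams(0.5, 0.0, 0.2),
                                      hybrid_session, "hybrid")
        assert nll == pytest.approx(160 * np.log(2), abs=1e-9)

    def test_hybrid_with_eta_zero_equals_qlearning(self, hybrid_session):
        p = AgentParams(0.3, 5.0, 0.0)
        a = negative_log_likelihood(p, hybrid_session, "hybrid")
        b = negative_log_likelihood(p, hybrid_session, "qlearning")
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_naive_reference_on_random_pairs(self, cfg):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = random_params(rng)
            s = simulate_session(p, cfg, rng)
            got = negative_log_likelihood(p, s, "hybrid")
            want = naive_ref.negative_log_likelihood(
                s.choices, s.outcomes, p.alpha0, p.beta, p.eta)
            assert got == pytest.approx(want, abs=1e-10)

    def test_multiple_sessions_sum_with_state_reset(self, cfg):
        rng = np.random.default_rng(9)
        p = AgentParams(0.2, 3.0, 0.1)
        s1 = simulate_session(p, cfg, rng)
        s2 = simulate_session(p, cfg, rng)
        joint = negative_log_likelihood(p, [s1, s2], "hybrid")
        solo = sum(negative_log_likelihood(p, s, "hybrid") for s in (s1, s2))
        assert joint == pytest.approx(solo, abs=1e-9)

    def test_generating_params_beat_perturbed_params_on_average(self, cfg):
        gen = AgentParams(0.3, 5.0, 0.0)
        off = AgentParams(0.8, 1.0, 0.0)
        diffs = []
        for seed in range(50):
            s = simulate_session(gen, cfg, np.random.default_rng([70, seed]),
                                 model="qlearning")
            diffs.append(negative_log_likelihood(off, s, "qlearning")
                         - negative_log_likelihood(gen, s, "qlearning"))
        assert np.mean(diffs) > 0


class TestInformationCriteria:
    def test_aic_bic_formulas(self):
        aic, bic = information_criteria(-1379.0, 2, 2400)
        assert aic == 2762.0
        assert bic == pytest.approx(2758 + 2 * np.log(2400))

    def test_degenerate_single_datapoint(self):
        aic, bic = information_criteria(0.0, 3, 1)
        assert aic == 6.0
        assert bic == 0.0  # log 1 = 0

    def test_bic_penalizes_more_than_aic_beyond_e_squared(self):
        for N in (8, 100, 2400):
            aic, bic = information_criteria(-10.0, 3, N)
            assert bic > aic  # k log N > 2k whenever N > e^2

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            information_criteria(-1.0, 0, 10)
        with pytest.raises(ValueError):
            information_criteria(-1.0, 2, 0)


class TestLikelihoodRatioTest:
    def test_equal_likelihoods_give_zero_statistic(self):
        r = likelihood_ratio_test(_make_fit("qlearning", -100.0, 2, 160),
                                  _make_fit("hybrid", -100.0, 3, 160))
        assert r.statistic == 0.0 and r.p_value == 1.0 and r.df == 1

    def test_statistic_is_twice_loglik_difference(self):
        r = likelihood_ratio_test(_make_fit("qlearning", -1389.9, 2, 2400),
                                  _make_fit("hybrid", -1366.0, 3, 2400))
        assert r.statistic == pytest.approx(47.8)
        assert r.p_value < 0.001

    def test_negative_statistic_warns_and_clips(self):
        with pytest.warns(RuntimeWarning, match="negative"):
            r = likelihood_ratio_test(_make_fit("qlearning", -99.0, 2, 160),
                                      _make_fit("hybrid", -100.0, 3, 160))
        assert r.statistic == 0.0 and r.raw_statistic == pytest.approx(-2.0)
        assert r.p_value == 1.0

    def test_boundary_correction_halves_tail_probability(self):
        null, alt = _make_fit("qlearning", -102.0, 2, 160), _make_fit("hybrid", -100.0, 3, 160)
        plain = likelihood_ratio_test(null, alt)
        corr = likelihood_ratio_test(null, alt, boundary_correction=True)
        assert corr.p_value == pytest.approx(plain.p_value / 2)

    def test_mismatched_datasets_rejected(self):
        with pytest.raises(ValueError, match="n_obs"):
            likelihood_ratio_test(_make_fit("qlearning", -10.0, 2, 160),
                                  _make_fit("hybrid", -9.0, 3, 320))


class TestFitModel:
    def test_saturating_likelihood_pushes_beta_to_bound(self):
        # one option always rewarded, agent always takes it: the likelihood
        # keeps improving as beta grows, so the fit should hit the bound
        s = Session(choices=np.ones(160, dtype=int), outcomes=np.ones(160))
        f = fit_model(s, "qlearning", n_restarts=4, seed=0)
        # beyond beta ~ 28 the floored likelihood is exactly flat, so any
        # point on the plateau (up to the bound) is a global optimum
        assert f.params.beta > 25.0
        assert -f.log_likelihood < 5.0  # near-certain choices after onset
        at_bound = negative_log_likelihood(
            AgentParams(f.params.alpha0, 50.0), s, "qlearning")
        assert -f.log_likelihood == pytest.approx(at_bound, abs=1e-6)

    def test_group_recovery_from_many_sessions(self, cfg):
        gen = AgentParams(0.3, 5.0, 0.0)
        rng = np.random.default_rng(14)
        sessions = [simulate_session(gen, cfg, rng, model="qlearning")
                    for _ in range(200)]
        f = fit_model(sessions, "qlearning", n_restarts=5, seed=1)
        assert f.params.alpha0 == pytest.approx(0.3, abs=0.05)
        assert f.params.beta == pytest.approx(5.0, abs=1.0)
        assert f.n_obs == 200 * 160
        # AIC/BIC self-consistency with the reported likelihood
        aic, bic = information_criteria(f.log_likelihood, 2, f.n_obs)
        assert f.aic == pytest.approx(aic) and f.bic == pytest.approx(bic)

    def test_nesting_inequality_hybrid_at_least_qlearning(self, cfg):
        for seed in range(3):
            coh = generate_cohort(5, "qlearning", AgentParams(0.2, 4.0),
                                  cfg, seed=seed)
            fits = fit_both(coh.sessions, n_restarts=3, seed=seed)
            assert (fits["hybrid"].log_likelihood
                    >= fits["qlearning"].log_likelihood - 1e-6)

    def test_unknown_model_rejected(self, hybrid_session):
        with pytest.raises(ValueError, match="unknown model"):
            fit_model(hybrid_session, "actor-critic")


class TestGroupAndIndividualFits:
    def test_single_participant_group_equals_individual(self, cfg):
        coh = generate_cohort(1, "qlearning", AgentParams(0.3, 5.0), cfg, seed=5)
        tables = group_and_individual_fits(coh.sessions, n_restarts=4, seed=2)
        ind_q = tables.individual.query("model == 'qlearning'").iloc[0]
        assert tables.group["qlearning"].log_likelihood == pytest.approx(
            ind_q.log_likelihood, abs=1e-4)
        assert tables.group["qlearning"].n_obs == 160

    def test_group_n_uses_all_trials(self, cfg):
        coh = generate_cohort(3, "qlearning", AgentParams(0.3, 5.0), cfg, seed=6)
        tables = group_and_individual_fits(coh.sessions, n_restarts=3, seed=3)
        f = tables.group["qlearning"]
        assert f.n_obs == 3 * 160
        assert f.bic == pytest.approx(-2 * f.log_likelihood + 2 * np.log(480))

    def test_sessions_with_missing_trials_rejected_with_count(self, cfg):
        coh = generate_cohort(2, "qlearning", AgentParams(0.3, 5.0), cfg, seed=7)
        short = Session(choices=np.ones(150, dtype=int), outcomes=np.zeros(150),
                        participant_id="P03")
        with pytest.raises(ValueError, match="1 session"):
            group_and_individual_fits(coh.sessions + [short])
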