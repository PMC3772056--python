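"""Prospect-theory model, softmax, likelihood, BIC and logistic regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from valueframe import (
    LogisticChoiceModel,
    ObjectiveEVModel,
    ProspectModel,
    ProspectParams,
    choice_probability,
    compare_bic,
    generate_stimulus_set,
    logistic_choice_analysis,
    negative_log_likelihood,
    simulate_choices,
    subjective_value,
)
from valueframe.behavior import _weight_probability


class TestSubjectiveValue:
    def test_identity_parameters_give_objective_ev(self):
        p = ProspectParams(1.0, 1.0, 1.0)
        assert subjective_value(0.6, 50, p) == pytest.approx(30.0)

    def test_curvature_only(self):
        p = ProspectParams(0.5, 1.0, 1.0)
        # near-certain 100 units is worth about sqrt(100)
        assert subjective_value(1 - 1e-9, 100, p) == pytest.approx(10.0, rel=1e-6)

    def test_matches_independent_closed_forms(self):
        # hand-evaluated w and u for alpha=0.8, gamma=0.7, p=0.4, r=60
        gamma, alpha, p, r = 0.7, 0.8, 0.4, 60.0
        w = p**gamma / (p**gamma + (1 - p) ** gamma) ** (1 / gamma)
        u = r**alpha
        got = subjective_value(p, r, ProspectParams(alpha, gamma, 1.0))
        assert got == pytest.approx(w * u, rel=1e-12)

    def test_power_weighting_switch(self):
        p = ProspectParams(1.0, 0.5, 1.0, weighting="power")
        assert subjective_value(0.49, 10, p) == pytest.approx(0.7 * 10, rel=1e-9)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.2])
    def test_probability_domain_enforced(self, p):
        with pytest.raises(ValueError):
            subjective_value(p, 10, ProspectParams())


class TestChoiceProbability:
    def test_softmax_value(self):
        got = choice_probability([2.0, 1.0], 1.0)
        e = np.e
        assert got[0] == pytest.approx(e**2 / (e**2 + e))
        assert got[1] == pytest.approx(e / (e**2 + e))

    @given(st.floats(0.0, 50.0), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_equal_values_and_beta_zero_are_uniform(self, beta, v):
        assert choice_probability([v, v], beta)[0] == pytest.approx(0.5)
        assert choice_probability([v, v - 10], 0.0)[0] == pytest.approx(0.5)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=5),
           st.floats(0, 40))
    @settings(max_examples=100, deadline=None)
    def test_sums_to_one_and_overflow_safe(self, values, beta):
        p = choice_probability(values, beta)
        assert np.isfinite(p).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_own_value(self):
        p_lo = choice_probability([1.0, 2.0], 1.5)[0]
        p_hi = choice_probability([1.5, 2.0], 1.5)[0]
        assert p_hi > p_lo


class TestNLL:
    def test_single_even_trial(self):
        # symmetric options -> P(choice)=0.5 -> NLL = ln 2
        trials = pd.DataFrame(
            {"p1": [0.5], "m1": [50.0], "p2": [0.5], "m2": [50.0], "choice": [1]}
        )
        got = negative_log_likelihood(trials, ProspectParams(1, 1, 1))
        assert got == pytest.approx(np.log(2))

    def test_additivity(self, small_trials):
        params = ProspectParams(0.9, 0.8, 2.0)
        total = negative_log_likelihood(small_trials, params)
        parts = sum(
            negative_log_likelihood(small_trials.iloc[[i]], params)
            for i in range(len(small_trials))
        )
        assert total == pytest.approx(parts, rel=1e-10)

    def test_certain_choices_give_zero(self):
        trials = pd.DataFrame(
            {"p1": [0.9], "m1": [90.0], "p2": [0.1], "m2": [10.0], "choice": [1]}
        )
        assert negative_log_likelihood(trials, ProspectParams(1, 1, 50)) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_invariant_to_common_value_shift(self, small_trials):
        # handled through the softmax; verify via direct probability identity
        v = np.array([3.0, 1.0])
        p0 = choice_probability(v, 2.0)
        p1 = choice_probability(v + 100.0, 2.0)
        np.testing.assert_allclose(p0, p1, atol=1e-12)

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            negative_log_likelihood(pd.DataFrame(columns=["p1", "m1", "p2", "m2", "choice"]),
                                    ProspectParams())


class TestFitProspect:
    def test_refit_is_deterministic(self, small_trials):
        a = ProspectModel(small_trials).fit(n_restarts=4, seed=3)
        b = ProspectModel(small_trials).fit(n_restarts=4, seed=3)
        assert a.params == b.params and a.nll == b.nll

    def test_beta_zero_data_recovers_flat_choice(self):
        trials = generate_stimulus_set(n_per_type=200, seed=5)
        trials = simulate_choices(trials, ProspectParams(1, 1, 0.0), seed=6)
        fit = ProspectModel(trials).fit(n_restarts=6, seed=0)
        # likelihood near n*ln2 and fitted choice probabilities near chance
        # (alpha/gamma are unidentified; only effective stochasticity matters)
        assert fit.nll == pytest.approx(len(trials) * np.log(2), rel=0.02)
        v1 = subjective_value(trials.p1, trials.m1, fit.params)
        v2 = subjective_value(trials.p2, trials.m2, fit.params)
        probs = choice_probability(np.stack([v1, v2], axis=-1), fit.params.beta)
        assert np.abs(probs[:, 0] - 0.5).max() < 0.1

    def test_bic_bookkeeping(self, small_trials):
        fit = ProspectModel(small_trials).fit(n_restarts=3, seed=0)
        assert fit.bic == pytest.approx(3 * np.log(fit.n_trials) + 2 * fit.nll)
        base = ObjectiveEVModel(small_trials).fit(seed=0)
        # equal NLLs would differ by (3-1) ln n
        assert (fit.bic - 2 * fit.nll) - (base.bic - 2 * base.nll) == pytest.approx(
            2 * np.log(len(small_trials))
        )

    def test_recovery_from_known_generator(self, full_trials, agent_params):
        fit = ProspectModel(full_trials).fit(n_restarts=10, seed=0)
        assert fit.params.alpha == pytest.approx(agent_params.alpha, abs=0.15)
        assert fit.params.beta == pytest.approx(agent_params.beta, rel=0.5)


class TestCompareBic:
    def test_prospect_data_favours_prospect(self):
        trials = generate_stimulus_set(n_per_type=324, seed=31)
        trials = simulate_choices(trials, ProspectParams(0.5, 0.7, 2.0), seed=32)
        rec = compare_bic(trials, n_restarts=8, seed=0)
        assert rec["preferred"] == "prospect"

    def test_ev_data_favours_simpler_model(self):
        trials = generate_stimulus_set(n_per_type=324, seed=33)
        trials = simulate_choices(trials, ProspectParams(1.0, 1.0, 0.1), seed=34)
        rec = compare_bic(trials, n_restarts=8, seed=0)
        assert rec["preferred"] == "objective_ev"


def _irls_logistic(X, y, n_iter=100, tol=1e-12):
    """Independent IRLS reimplementation for the oracle comparison."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        z = eta + (y - mu) / np.maximum(w, 1e-12)
        new = np.linalg.solve((X.T * w) @ X, (X.T * w) @ z)
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


class TestLogisticChoice:
    def test_matches_irls_oracle(self, rng):
        for _ in range(3):
            trials = generate_stimulus_set(n_per_type=150,
                                           seed=int(rng.integers(2**31 - 1)))
            trials = simulate_choices(trials, ProspectParams(0.8, 0.9, 0.3),
                                      seed=int(rng.integers(2**31 - 1)))
            model = LogisticChoiceModel(trials)
            fit = model.fit()
            assert not fit["separated"]
            oracle = _irls_logistic(model.exog, model.endog)
            got = np.array([fit["coefs"][n] for n in model.regressor_names])
            np.testing.assert_allclose(got, oracle, atol=1e-6)

    def test_probability_driven_choices_load_on_probability(self):
        rng = np.random.default_rng(77)
        sessions = {}
        for s in range(8):
            trials = generate_stimulus_set(n_per_type=150, seed=100 + s)
            noise = rng.normal(0, 0.5, len(trials))
            trials["choice"] = np.where(
                (trials["p1"] - trials["p2"]) + noise > 0, 1, 2
            )
            sessions[f"s{s}"] = trials
        res = logistic_choice_analysis(sessions)
        for tt in ("comparison", "sequential"):
            t_dp = res["one_sample_t"][tt]["dp"]
            assert t_dp["statistic"] > 0 and t_dp["pvalue"] < 0.01

    def test_second_option_bias_shows_in_constant(self):
        sessions = {}
        for s in range(6):
            trials = generate_stimulus_set(n_per_type=120, seed=200 + s)
            trials = simulate_choices(
                trials, ProspectParams(0.8, 0.7, 3.0), order_bias=50.0, seed=300 + s
            )
            sessions[f"s{s}"] = trials
        res = logistic_choice_analysis(sessions)
        # option 2 is always chosen on sequential trials -> negative constant
        # for P(choose option 1), flagged as separated
        consts = res["coefficients"]["sequential"]["const"]
        assert (consts < 0).all()
        assert any(res["separated"]["sequential"])

    def test_random_choice_null_calibration(self):
        rng = np.random.default_rng(9)
        rejections, n_mc = 0, 40
        for b in range(n_mc):
            sessions = {}
            for s in range(6):
                trials = generate_stimulus_set(n_per_type=80, seed=1000 + 20 * b + s)
                trials["choice"] = rng.choice([1, 2], size=len(trials))
                sessions[f"s{s}"] = trials
            res = logistic_choice_analysis(sessions)
            ps = [res["one_sample_t"][tt][n]["pvalue"]
                  for tt in ("comparison", "sequential")
                  for n in ("dp", "dr", "dev")]
            rejections += sum(p < 0.05 for p in ps)
        rate = rejections / (n_mc * 6)
        # per-test type-I error should sit near 5%
        assert rate < 0.12
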