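"""Grid Bayesian fitting, BIC, model selection, generate-recover."""

import numpy as np
import pytest
from scipy.stats import logistic

from socialug.decision import GridSpec, get_model, trial_values
from socialug.inference import (PROB_FLOOR, ParameterGrid, bic, build_grid,
                                fit_model, generate_recover,
                                grid_log_likelihood, model_policy,
                                predictive_accuracy, select_models)
from socialug.task_engine import run_session

from conftest import make_session


def brute_loglik(spec, session, eps, grid, context=None):
    """Independent enumeration oracle using scipy's stable logistic logcdf."""
    import itertools
    c = session["choice"].to_numpy(float)
    out = np.empty(grid.shape)
    floor = np.log(PROB_FLOOR)
    for idx in itertools.product(*(range(n) for n in grid.shape)):
        params = {name: grid.nodes[i][idx[i]] for i, name in enumerate(grid.names[:-1])}
        beta = grid.nodes[-1][idx[-1]]
        v = trial_values(spec, session, eps, params, context)
        lq = np.maximum(logistic.logcdf(beta * v), floor)
        l1q = np.maximum(logistic.logcdf(-beta * v), floor)
        out[idx] = np.sum(c * lq + (1 - c) * l1q)
    return out


class TestGridLogLikelihood:
    def test_matches_brute_force_enumeration(self):
        spec = get_model(4)
        sess = make_session([200, 500, 800], [0, 1, 1])
        eps = sess["phi"].to_numpy()
        grid = build_grid(spec, 5)
        ll, _ = grid_log_likelihood(spec, sess, eps, grid)
        brute = brute_loglik(spec, sess, eps, grid)
        assert np.abs(ll - brute).max() < 1e-9

    def test_single_accept_trial_is_log_q(self):
        spec = get_model(4)
        sess = make_session([700], [1])
        grid = ParameterGrid(("kappa", "omega", "beta"),
                             (np.array([1.0]), np.array([0.5]), np.array([2.0])))
        ll, _ = grid_log_likelihood(spec, sess, sess["phi"].to_numpy(), grid)
        v = 1.0 * 7.0 - 0.5 * 4.0        # pounds
        expected = float(logistic.logcdf(2.0 * v))
        assert ll.ravel()[0] == pytest.approx(expected, abs=1e-12)

    def test_vanishing_beta_gives_chance_likelihood(self):
        spec = get_model(4)
        sess = make_session([200, 500, 800, 300], [0, 1, 1, 0])
        grid = ParameterGrid(("kappa", "omega", "beta"),
                             (np.array([1.0]), np.array([2.0]), np.array([1e-14])))
        ll, _ = grid_log_likelihood(spec, sess, sess["phi"].to_numpy(), grid)
        assert ll.ravel()[0] == pytest.approx(4 * np.log(0.5), abs=1e-9)

    def test_empty_session_rejected(self):
        spec = get_model(4)
        sess = make_session([500], [1]).iloc[:0]
        with pytest.raises(ValueError):
            grid_log_likelihood(spec, sess, np.array([]))


class TestFitModel:
    def test_posterior_normalised_and_matches_brute(self):
        spec = get_model(10)
        sess = make_session([200, 450, 650, 900, 350], [0, 1, 1, 0, 1],
                            phis=[0.1, 0.5, 0.9, 0.3, 0.7])
        eps = sess["phi"].to_numpy()
        fit = fit_model(spec, sess, eps, grid_points=5)
        assert fit.posterior.sum() == pytest.approx(1.0, abs=1e-10)
        brute = brute_loglik(spec, sess, eps, fit.grid)
        bpost = np.exp(brute - brute.max())
        bpost /= bpost.sum()
        assert np.abs(fit.posterior - bpost).max() < 1e-12

    def test_flat_likelihood_returns_prior_midpoints(self):
        # zero liking coefficients make every decision value 0: q = 0.5
        spec = get_model(3)
        sess = make_session([200, 500, 800], [0, 1, 1])
        from socialug.perception import LikingParams
        ctx = {"liking": LikingParams(0, 0, 0)}
        fit = fit_model(spec, sess, sess["phi"].to_numpy(), context=ctx,
                        grid_points=9)
        nodes = fit.grid.nodes[0]
        assert fit.params["beta"] == pytest.approx(nodes.mean(), rel=1e-9)
        assert np.allclose(fit.posterior, 1.0 / len(nodes))

    def test_bic_uses_grid_maximum(self):
        spec = get_model(4)
        sess = make_session([200, 500, 800], [0, 1, 1])
        fit = fit_model(spec, sess, sess["phi"].to_numpy(), grid_points=7)
        assert fit.bic == pytest.approx(spec.k * np.log(3) - 2 * fit.max_loglik)


class TestBic:
    def test_closed_form(self):
        assert bic(-100, 3, 240) == pytest.approx(3 * np.log(240) + 200)
        assert bic(-100, 3, 240) == pytest.approx(216.4418, abs=1e-3)

    def test_zero_parameters_zero_loglik(self):
        assert bic(0.0, 0, 10) == 0.0

    def test_useless_parameter_costs_log_n(self):
        assert bic(-50, 4, 240) - bic(-50, 3, 240) == pytest.approx(np.log(240))


class TestPredictiveAccuracy:
    def test_aligned_and_antialigned(self):
        spec = get_model(4)
        sess = make_session([200, 500, 800, 100], [0, 1, 1, 0])
        params = {"kappa": 1.0, "omega": 1.0, "beta": 5.0}
        # v = R_S - D (pounds): negative below 500, positive at/above
        assert predictive_accuracy(spec, params, sess, sess["phi"].to_numpy()) == 1.0
        anti = sess.copy()
        anti["choice"] = 1 - anti["choice"]
        assert predictive_accuracy(spec, params, anti, sess["phi"].to_numpy()) == 0.0


class TestSelectModels:
    @staticmethod
    def _fake_fit(model_id, bic_value):
        from socialug.inference import FitResult
        return FitResult(model_id=model_id, model_name=str(model_id), params={},
                         max_loglik=0.0, bic=bic_value, accuracy=0.5,
                         n_trials=240, q_accept=np.array([]))

    def test_dominant_model_takes_exceedance(self):
        fits = {1: [self._fake_fit(1, 100.0)] * 10,
                2: [self._fake_fit(2, 110.0)] * 10}
        sel = select_models(fits, seed=0)
        assert sel["best_bic"] == 1
        assert sel["exceedance"][1] > 0.99
        assert sum(sel["exceedance"].values()) == pytest.approx(1.0, abs=1e-6)

    def test_identical_evidence_splits_evenly(self):
        fits = {m: [self._fake_fit(m, 100.0)] * 6 for m in (1, 2, 3)}
        sel = select_models(fits, seed=0)
        freqs = list(sel["expected_freq"].values())
        assert np.allclose(freqs, 1 / 3, atol=1e-6)

    def test_mismatched_participants_rejected(self):
        fits = {1: [self._fake_fit(1, 100.0)] * 3,
                2: [self._fake_fit(2, 100.0)] * 4}
        with pytest.raises(ValueError):
            select_models(fits)


class TestGenerateRecover:
    def test_deterministic_given_seed(self):
        a = generate_recover(10, n_iterations=2, seed=5, grid_points=7,
                             n_blocks=1, trials_per_block=30)
        b = generate_recover(10, n_iterations=2, seed=5, grid_points=7,
                             n_blocks=1, trials_per_block=30)
        for name in a["params"]:
            np.testing.assert_array_equal(a["params"][name]["recovered"],
                                          b["params"][name]["recovered"])

    def test_report_structure(self):
        rep = generate_recover(10, n_iterations=3, seed=1, grid_points=7,
                               n_blocks=1, trials_per_block=20)
        assert set(rep["params"]) == {"kappa", "omega", "beta"}
        for d in rep["params"].values():
            assert len(d["true"]) == 3 and len(d["recovered"]) == 3


class TestModelPolicy:
    def test_deterministic_policy_matches_argmax(self):
        spec = get_model(4)
        params = {"kappa": 1.0, "omega": 1.0, "beta": 2.0}
        pol = model_policy(spec, params, stochastic=False)
        # v = R_S - D in pounds: sign flips at offer 1000/3
        assert pol(0.5, 600, []) == 1
        assert pol(0.5, 250, []) == 0
        # zero value ties break toward accept
        zero = model_policy(spec, {"kappa": 0.0, "omega": 0.0, "beta": 2.0},
                            stochastic=False)
        assert zero(0.5, 250, []) == 1
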