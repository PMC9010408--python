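"""Model-free behavioural statistics."""

import numpy as np
import pandas as pd
import pytest

from socialug.behaviour import (acceptance_grid, expected_outcome,
                                history_design, history_logistic,
                                history_logistic_cohort, main_effects_ols,
                                misprediction_analysis, misprediction_cohort,
                                parameter_covariates_ols, vif)
from socialug.task_engine import (accept_all_policy, offer_threshold_policy,
                                  run_session)

from conftest import make_session


class TestAcceptanceGrid:
    def test_accept_everything_gives_ones(self):
        s = run_session(accept_all_policy, seed=0)
        g = acceptance_grid(s)
        assert np.all(g.prob[g.counts > 0] == 1.0)

    def test_threshold_policy_partitions_grid(self):
        s = run_session(offer_threshold_policy(500), seed=1)
        g = acceptance_grid(s)
        offers = g.space.offers
        visited = g.counts > 0
        below = visited & (offers[None, :] < 500)
        above = visited & (offers[None, :] >= 500)
        assert np.all(g.prob[below] == 0.0)
        assert np.all(g.prob[above] == 1.0)

    def test_counts_conserve_trials(self, one_session):
        g = acceptance_grid(one_session)
        assert g.counts.sum() == 240

    def test_probabilities_recomputable_from_raw_session(self, one_session):
        g = acceptance_grid(one_session)
        cells = g.cells()
        for _, row in cells.head(10).iterrows():
            mask = ((one_session["phi"] == row["phi"])
                    & (one_session["offer_pence"] == row["offer_pence"]))
            assert one_session.loc[mask, "choice"].mean() == pytest.approx(row["prob"])


class TestMainEffects:
    @staticmethod
    def _policy_cohort(policy_factory, n=20, seed0=100):
        return [run_session(policy_factory(np.random.default_rng(seed0 + i)),
                            seed=seed0 + i) for i in range(n)]

    def test_offer_only_effect_detected(self):
        def factory(rng):
            return lambda phi, offer, h: int(rng.random() < offer / 1000)
        grids = [acceptance_grid(s) for s in self._policy_cohort(factory)]
        rep = main_effects_ols(grids)
        g = rep["group"].set_index("regressor")
        assert g.loc["offer", "t"] > 6
        assert abs(g.loc["face", "t"]) < 3

    def test_constant_acceptance_gives_zero_slopes(self):
        def factory(rng):
            return lambda phi, offer, h: int(rng.random() < 0.5)
        grids = [acceptance_grid(s) for s in self._policy_cohort(factory, n=8)]
        # slopes not exactly zero per participant (binomial noise), but the
        # group means should be statistically null
        rep = main_effects_ols(grids)
        g = rep["group"].set_index("regressor")
        assert abs(g.loc["offer", "t"]) < 4
        assert abs(g.loc["face", "t"]) < 4

    def test_interaction_effect_detected(self):
        def factory(rng):
            return lambda phi, offer, h: int(rng.random() < np.clip(phi * offer / 600, 0, 1))
        grids = [acceptance_grid(s) for s in self._policy_cohort(factory, n=30)]
        rep = main_effects_ols(grids)
        g = rep["group"].set_index("regressor")
        assert g.loc["face_x_offer", "t"] > 0
        assert g.loc["face_x_offer", "p"] < 0.05


class TestHistoryLogistic:
    def test_design_shape_and_block_boundaries(self, one_session):
        X, y, names = history_design(one_session, lags=3)
        assert X.shape[1] == 12 and len(names) == 12
        # 3 trials dropped per block
        assert len(y) == 240 - 3 * 6
        assert np.abs(X.mean(axis=0)).max() < 1e-10

    def test_planted_previous_offer_rule(self):
        rng = np.random.default_rng(0)
        history_state = {"prev": 500}

        def policy(phi, offer, h):
            c = int(history_state["prev"] > 500)
            history_state["prev"] = offer
            return c
        s = run_session(policy, seed=0)
        fit = history_logistic(s)
        coefs = dict(zip(fit["names"], fit["coefficients"]))
        assert coefs["offer_lag1"] == max(coefs.values())
        assert coefs["offer_lag1"] > 0

    def test_random_choices_yield_null_group_tests(self):
        sessions = []
        for i in range(25):
            rng = np.random.default_rng(300 + i)
            sessions.append(run_session(lambda p, o, h: int(rng.random() < 0.5),
                                        seed=300 + i))
        rep = history_logistic_cohort(sessions)
        # no regressor should be strongly significant under the null
        assert np.abs(rep["group"]["t"]).max() < 5


class TestVif:
    def test_orthogonal_design_unit_vif(self):
        # centred, mutually orthogonal contrast columns
        x1 = np.array([1, 1, 1, 1, -1, -1, -1, -1], float)
        x2 = np.array([1, 1, -1, -1, 1, 1, -1, -1], float)
        x3 = np.array([1, -1, 1, -1, 1, -1, 1, -1], float)
        out = vif(np.column_stack([x1, x2, x3]))
        np.testing.assert_allclose(out["vif"], 1.0, atol=1e-9)

    def test_duplicated_regressor_flagged(self):
        x = np.random.default_rng(0).normal(size=20)
        out = vif(np.column_stack([x, x]))
        assert out["collinear"].all()

    def test_known_correlation_closed_form(self):
        # construct two columns with exact sample correlation 0.6
        n = 50
        rng = np.random.default_rng(1)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)       # orthogonalise
        b /= b.std()
        y = 0.6 * a + np.sqrt(1 - 0.36) * b
        out = vif(np.column_stack([a, y]))
        np.testing.assert_allclose(out["vif"], 1 / (1 - 0.36), rtol=1e-9)


class TestMisprediction:
    def test_perfect_predictions_flag_empty_set(self, one_session):
        rep = misprediction_analysis(one_session["choice"].to_numpy(), one_session)
        assert rep["n_mispredicted"] == 0
        np.testing.assert_allclose(rep["coefficients"][1:], 0.0, atol=1e-12)

    def test_planted_interaction_failure_detected(self, small_cohort):
        sessions = [p.session for p in small_cohort]
        preds = []
        for s in sessions:
            p = s["choice"].to_numpy().copy()
            # model fails at extreme-face x unfair-offer cells
            zone = (s["phi"].to_numpy() > 0.7) & (s["offer_pence"].to_numpy() < 400)
            p[zone] = 1 - p[zone]
            preds.append(p)
        rep = misprediction_cohort(preds, sessions)
        g = rep["group"].set_index("regressor")
        assert g.loc["face_x_offer", "mean"] != 0

    def test_random_mispredictions_are_null(self, small_cohort):
        sessions = [p.session for p in small_cohort]
        rng = np.random.default_rng(9)
        preds = []
        for s in sessions:
            p = s["choice"].to_numpy().copy()
            flip = rng.random(len(p)) < 0.1
            p[flip] = 1 - p[flip]
            preds.append(p)
        rep = misprediction_cohort(preds, sessions)
        assert np.abs(rep["group"]["t"][1:]).max() < 5


class TestParameterCovariates:
    def test_planted_negative_correlation_recovered(self):
        rng = np.random.default_rng(2)
        n = 60
        omega = rng.uniform(-4, -1, n)
        svo = -10 * omega + rng.normal(0, 4, n)   # higher svo <-> more negative? sign below
        cov = pd.DataFrame({"svo": svo, "mood": rng.normal(size=n)})
        rep = parameter_covariates_ols(omega, cov)
        i = rep["names"].index("svo")
        assert rep["coefficients"][i] < 0
        assert rep["p"][i] < 0.01

    def test_independent_covariates_null(self):
        rng = np.random.default_rng(3)
        n = 40
        omega = rng.uniform(-4, -1, n)
        cov = pd.DataFrame({"svo": rng.normal(size=n), "mood": rng.normal(size=n)})
        rep = parameter_covariates_ols(omega, cov)
        assert np.abs(rep["t"][1:]).max() < 4

    def test_intercept_equals_mean_parameter(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(1.5, 0.3, 30)
        cov = pd.DataFrame({"svo": rng.normal(size=30)})
        rep = parameter_covariates_ols(vals, cov)
        assert rep["coefficients"][0] == pytest.approx(vals.mean(), abs=1e-9)


class TestExpectedOutcome:
    def test_accept_all_fair(self):
        s = make_session([500] * 25, [1] * 25)
        assert expected_outcome(s) == pytest.approx(500.0)

    def test_reject_all(self):
        s = make_session([500] * 25, [0] * 25)
        assert expected_outcome(s) == 0.0

    def test_half_acceptance(self):
        s = make_session([400] * 20, [1, 0] * 10)
        assert expected_outcome(s) == pytest.approx(200.0)
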