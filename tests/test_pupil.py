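"""Pupil preprocessing, design construction and time-resolved regression."""

import numpy as np
import pandas as pd
import pytest

from socialug import pupil
from socialug.pupil import (BASELINE_S, DT_MS, RESPONSE_S, SAMPLING_HZ,
                            DESIGN_COLUMNS, binned_ttests, build_design,
                            preprocess, timepoint_regression)
from socialug.filtering import session_filter_regressors
from socialug.synth import default_coef_profiles, synth_epochs, synth_pupil

from conftest import make_session


def _small_design(n_trials=24, seed=0):
    rng = np.random.default_rng(seed)
    sess = make_session(rng.choice(np.arange(50, 1000, 50), n_trials),
                        rng.integers(0, 2, n_trials),
                        phis=rng.choice(np.arange(1, 10) / 10, n_trials))
    regs = pd.DataFrame({c: rng.normal(size=n_trials)
                         for c in ["surprise_offer", "surprise_face", "vol_offer",
                                   "vol_face", "noise_offer", "noise_face"]})
    design = build_design(sess, {"kappa": 1.2, "omega": -2.0}, regs)
    return sess, regs, design


class TestPreprocess:
    def test_constant_trace_gives_zero_epochs(self):
        sess = make_session([500] * 3, [1, 0, 1])
        design = build_design(sess, {"kappa": 1.0, "omega": -1.0},
                              pd.DataFrame({c: np.zeros(3) for c in
                                            ["surprise_offer", "surprise_face",
                                             "vol_offer", "vol_face",
                                             "noise_offer", "noise_face"]}))
        samples, events = synth_pupil(design, profiles={c: np.zeros(2250) for c in design.columns},
                                      noise_sd=0.0, blink_rate_hz=0.0)
        samples["pupil"] = 3.14      # constant raw trace
        with pytest.warns(UserWarning):
            ep = preprocess(samples, events)
        assert np.allclose(ep.data[np.isfinite(ep.data)], 0.0)

    def test_interpolated_outcome_exclusion_rule(self):
        sess, regs, design = _small_design(4)
        samples, events = synth_pupil(design, noise_sd=0.05, blink_rate_hz=0.0, seed=1)
        # corrupt 60% of trial 2's outcome window, 40% of trial 3's
        t0 = samples["time_ms"].iloc[0]
        win = int(1.5 * SAMPLING_HZ)
        for trial, frac in ((2, 0.6), (3, 0.4)):
            oc_ms = events.query("trial == @trial and event_name == 'outcome'")["time_ms"].iloc[0]
            oc = int((oc_ms - t0) // DT_MS)
            samples.loc[oc:oc + int(frac * win) - 1, "valid"] = 0
        ep = preprocess(samples, events)
        assert not ep.included[1]        # 60% interpolated -> excluded
        assert ep.included[2]            # 40% interpolated -> kept
        assert ep.included[0] and ep.included[3]

    def test_lowpass_attenuates_fast_oscillation(self):
        # feed unit-amplitude sinusoids through the pipeline; the session
        # z-transform absorbs the post-filter amplitude into z_sd, so the
        # z_sd ratio measures the filter's relative attenuation
        sds = {}
        for hz in (0.5, 10.0):
            sess, regs, design = _small_design(6)
            samples, events = synth_pupil(
                design, profiles={c: np.zeros(2250) for c in design.columns},
                noise_sd=0.0, blink_rate_hz=0.0)
            t = samples["time_ms"].to_numpy() / 1000.0
            samples["pupil"] = np.sin(2 * np.pi * hz * t)
            sds[hz] = preprocess(samples, events).z_sd
        assert 20 * np.log10(sds[0.5] / sds[10.0]) >= 20

    def test_overwhelmingly_missing_session_aborts(self):
        sess, regs, design = _small_design(3)
        samples, events = synth_pupil(design, noise_sd=0.05, blink_rate_hz=0.0)
        samples["valid"] = 0
        samples.loc[:len(samples) // 3, "valid"] = 1
        with pytest.raises(ValueError):
            preprocess(samples, events)


class TestBuildDesign:
    def test_eleven_demeaned_columns(self):
        sess, regs, design = _small_design()
        assert list(design.columns) == DESIGN_COLUMNS
        assert np.abs(design[DESIGN_COLUMNS[1:]].mean()).max() < 1e-10
        assert (design["constant"] == 1).all()

    def test_value_column_is_kappa_times_self_reward(self):
        sess, regs, design = _small_design()
        raw = 1.2 * sess["offer_pence"].to_numpy() / 100
        np.testing.assert_allclose(design["value_self"], raw - raw.mean(), atol=1e-12)

    def test_neutral_faces_zero_emotion_regressor(self):
        sess = make_session([400] * 6, [1] * 6, phis=[0.4] * 6)
        regs = pd.DataFrame({c: np.arange(6.0) for c in
                             ["surprise_offer", "surprise_face", "vol_offer",
                              "vol_face", "noise_offer", "noise_face"]})
        design = build_design(sess, {"kappa": 1.0, "omega": -2.0}, regs)
        np.testing.assert_allclose(design["emotion_modulation"], 0.0, atol=1e-12)


class TestTimepointRegression:
    def test_noiseless_profiles_recovered_exactly(self):
        sess, regs, design = _small_design(30)
        profiles = default_coef_profiles(np.arange(2250) * DT_MS)
        ep = synth_epochs(design, profiles, noise_sd=0.0)
        out = timepoint_regression(ep, design)
        i = DESIGN_COLUMNS.index("inequality")
        assert np.abs(out["coefficients"][i] - profiles["inequality"]).max() < 1e-6

    def test_flat_injected_coefficient_recovered_with_noise(self):
        sess, regs, design = _small_design(120, seed=3)
        profiles = {c: np.zeros(500) for c in DESIGN_COLUMNS}
        profiles["inequality"] = np.full(500, 0.5)
        ep = synth_epochs(design, profiles, noise_sd=0.1, seed=5)
        out = timepoint_regression(ep, design)
        i = DESIGN_COLUMNS.index("inequality")
        assert np.abs(out["coefficients"][i] - 0.5).max() < 0.05

    def test_constant_epochs_load_only_the_intercept(self):
        sess, regs, design = _small_design(20)
        ep = synth_epochs(design, {c: (np.full(100, 2.0) if c == "constant"
                                       else np.zeros(100))
                                   for c in DESIGN_COLUMNS})
        out = timepoint_regression(ep, design)
        np.testing.assert_allclose(out["coefficients"][0], 2.0, atol=1e-9)
        np.testing.assert_allclose(out["coefficients"][1:], 0.0, atol=1e-9)

    def test_matches_normal_equations(self):
        sess, regs, design = _small_design(40, seed=8)
        rng = np.random.default_rng(11)
        ep = synth_epochs(design, default_coef_profiles(np.arange(200) * DT_MS),
                          noise_sd=0.2, seed=12)
        out = timepoint_regression(ep, design)
        X = design.to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ ep.data)
        assert np.abs(out["coefficients"] - beta).max() < 1e-9


class TestBinnedTtests:
    def test_zero_coefficients_give_null_stats(self):
        C = np.zeros((5, 2, 1000))
        times = np.arange(1000) * DT_MS
        out = binned_ttests(C, times, ["a", "b"])
        assert (out["t"] == 0).all() and (out["p"] == 1).all()

    def test_single_participant_flagged_undefined(self):
        C = np.random.default_rng(0).normal(size=(1, 2, 500))
        out = binned_ttests(C, np.arange(500) * DT_MS, ["a", "b"])
        assert out["t"].isna().all()
        assert (out["df"] == 0).all()

    def test_planted_first_second_peak_detected(self):
        rng = np.random.default_rng(42)
        times = np.arange(2250) * DT_MS
        profile = np.where(times < 1000, 0.5, 0.05)
        C = rng.normal(0, 0.05, size=(12, 1, 2250)) + profile
        out = binned_ttests(C, times, ["inequality"])
        first = out[(out["bin_start_s"] == 0.0)].iloc[0]
        assert first["p"] < 0.01 and first["t"] > 0
        later = out[out["bin_start_s"] >= 2.0]
        assert (first["mean"] > later["mean"]).all()
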