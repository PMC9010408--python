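"""Pupil preprocessing and the time-resolved regression of pupil size.

Raw 500 Hz pupil-area traces are cleaned (linear interpolation across
blinks, zero-phase 3rd-order Butterworth low-pass at 3.75 Hz, session-wide
z-transform), epoched around offer presentation (7.5 s baseline before the
offer, 4.5 s response window after it) and baseline-corrected per trial.
Trials in which more than half of the outcome period was interpolated are
excluded.

The cleaned epochs are then regressed, independently at every 2-ms time
point, on an 11-column trial-wise design: a constant; the trial index (a
fatigue proxy); the model-derived self-reward value kappa*R_S; the
emotion-modulated inequality weight (omega + (eps - mu)^2); the inequality
magnitude |R_S - R_O|; and the six Bayesian-filter nuisance regressors
(surprise / volatility / noise for offers and faces).  All non-constant
regressors are demeaned, so coefficients are directly comparable.  Group
inference bins each coefficient time course at 1 s and applies one-sample
t-tests across participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy import stats

from .perception import MU_CROSSOVER

__all__ = [
    "SAMPLING_HZ",
    "BASELINE_S",
    "RESPONSE_S",
    "PupilEpochs",
    "preprocess",
    "DESIGN_COLUMNS",
    "build_design",
    "timepoint_regression",
    "binned_ttests",
]

SAMPLING_HZ = 500
DT_MS = 1000 // SAMPLING_HZ           # 2 ms
BASELINE_S = 7.5
RESPONSE_S = 4.5
LOWPASS_HZ = 3.75
BUTTER_ORDER = 3
EXCLUDE_INTERP_FRAC = 0.5
OUTCOME_WINDOW_S = 1.5                # outcome period screened for artefacts

DESIGN_COLUMNS = [
    "constant", "trial_index", "value_self", "emotion_modulation",
    "inequality", "surprise_offer", "surprise_face",
    "vol_offer", "vol_face", "noise_offer", "noise_face",
]


@dataclass
class PupilEpochs:
    """Baseline-corrected per-trial response epochs.

    ``data`` is (n_trials, n_timepoints) at 2 ms resolution from offer
    onset; excluded trials keep their rows but are masked out of every
    analysis through ``included``.
    """

    data: np.ndarray
    times_ms: np.ndarray
    trials: np.ndarray
    included: np.ndarray
    interp_frac_outcome: np.ndarray
    baseline_span_s: np.ndarray
    #: session mean/SD absorbed by the z-transform; multiply fitted
    #: coefficients by ``z_sd`` to express them in raw trace units
    z_mean: float = 0.0
    z_sd: float = 1.0

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


def _interpolate_invalid(pupil: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation across invalid stretches (blinks, dropouts)."""
    x = pupil.astype(float).copy()
    good = valid.astype(bool)
    if not good.any():
        raise ValueError("no valid samples in the session")
    idx = np.arange(len(x))
    x[~good] = np.interp(idx[~good], idx[good], x[good])
    return x


def preprocess(samples: pd.DataFrame, events: pd.DataFrame,
               session_trials: np.ndarray | None = None) -> PupilEpochs:
    """Clean a raw sample stream and cut baseline-corrected epochs.

    ``samples`` needs columns ``time_ms``, ``pupil``, ``valid`` (0/1) at
    500 Hz; ``events`` needs ``trial``, ``event_name``, ``time_ms`` with at
    least ``offer_onset`` and ``outcome`` markers per trial.
    """
    t = samples["time_ms"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    pupil = samples["pupil"].to_numpy(float)
    valid = samples["valid"].to_numpy(bool)
    frac_missing = 1.0 - valid.mean()
    if frac_missing > 0.5:
        raise ValueError(
            f"{frac_missing:.0%} of the session is missing/invalid; "
            "session unusable")

    clean = _interpolate_invalid(pupil, valid)
    nyq = SAMPLING_HZ / 2.0
    b, a = signal.butter(BUTTER_ORDER, LOWPASS_HZ / nyq, btype="low")
    filt = signal.filtfilt(b, a, clean)
    sd = filt.std()
    if sd == 0:
        warnings.warn("constant pupil trace; z-transform set to zeros")
        z = np.zeros_like(filt)
    else:
        z = (filt - filt.mean()) / sd

    offers = events[events["event_name"] == "offer_onset"].set_index("trial")["time_ms"]
    outcomes = events[events["event_name"] == "outcome"].set_index("trial")["time_ms"]
    if offers.empty:
        raise ValueError("no offer_onset events")
    trial_ids = (np.asarray(session_trials) if session_trials is not None
                 else offers.index.to_numpy())

    n_resp = int(RESPONSE_S * SAMPLING_HZ)
    t0 = t[0]
    epochs = np.full((len(trial_ids), n_resp), np.nan)
    included = np.zeros(len(trial_ids), dtype=bool)
    interp_frac = np.full(len(trial_ids), np.nan)
    base_span = np.full(len(trial_ids), np.nan)
    interpolated = ~valid

    for row, trial in enumerate(trial_ids):
        if trial not in offers.index:
            continue
        onset_ms = float(offers.loc[trial])
        if onset_ms < t0 or onset_ms > t[-1]:
            raise ValueError(f"offer_onset of trial {trial} outside sample range")
        onset = int(round((onset_ms - t0) / DT_MS))
        resp = z[onset:onset + n_resp]
        if len(resp) < n_resp:
            continue  # trial truncated at end of recording
        b0 = max(0, onset - int(BASELINE_S * SAMPLING_HZ))
        baseline = z[b0:onset]
        if len(baseline) == 0:
            continue
        base_span[row] = len(baseline) / SAMPLING_HZ
        epochs[row] = resp - baseline.mean()
        # artefact screen on the outcome period
        if trial in outcomes.index:
            oc = int(round((float(outcomes.loc[trial]) - t0) / DT_MS))
            oc_end = min(oc + int(OUTCOME_WINDOW_S * SAMPLING_HZ), len(z))
            window = interpolated[oc:oc_end]
        else:
            window = interpolated[onset:onset + n_resp]
        interp_frac[row] = window.mean() if len(window) else 1.0
        included[row] = interp_frac[row] <= EXCLUDE_INTERP_FRAC

    return PupilEpochs(
        data=epochs,
        times_ms=np.arange(n_resp) * DT_MS,
        trials=np.asarray(trial_ids),
        included=included,
        interp_frac_outcome=interp_frac,
        baseline_span_s=base_span,
        z_mean=float(filt.mean()),
        z_sd=float(sd),
    )


def build_design(session: pd.DataFrame, params: dict,
                 filter_regressors: pd.DataFrame,
                 epsilons: np.ndarray | None = None,
                 mu: float = MU_CROSSOVER) -> pd.DataFrame:
    """Trial-wise 11-regressor design for the pupillary regression.

    ``params`` carries the fitted kappa and omega of the best choice model
    (pound scale); ``epsilons`` defaults to the displayed valence.  All
    columns except the constant are demeaned.
    """
    eps = (np.asarray(epsilons, float) if epsilons is not None
           else session["phi"].to_numpy(float))
    rs = session["offer_pence"].to_numpy(float) / 100.0
    d = np.abs(session["offer_pence"].to_numpy(float)
               - session["other_pence"].to_numpy(float)) / 100.0
    X = pd.DataFrame({
        "constant": np.ones(len(session)),
        "trial_index": session["trial"].to_numpy(float),
        "value_self": params["kappa"] * rs,
        "emotion_modulation": params["omega"] + (eps - mu) ** 2,
        "inequality": d,
        "surprise_offer": filter_regressors["surprise_offer"].to_numpy(float),
        "surprise_face": filter_regressors["surprise_face"].to_numpy(float),
        "vol_offer": filter_regressors["vol_offer"].to_numpy(float),
        "vol_face": filter_regressors["vol_face"].to_numpy(float),
        "noise_offer": filter_regressors["noise_offer"].to_numpy(float),
        "noise_face": filter_regressors["noise_face"].to_numpy(float),
    })
    for col in DESIGN_COLUMNS[1:]:
        X[col] = X[col] - X[col].mean()
    return X


def timepoint_regression(epochs: PupilEpochs, design: pd.DataFrame,
                         min_trials: int = 10) -> dict:
    """Independent OLS at every 2-ms time point across included trials.

    Returns coefficient time series (n_regressors, n_timepoints) plus a
    flag when fewer than ``min_trials`` trials survive exclusion.
    """
    mask = epochs.included
    X = design.to_numpy(float)[mask]
    Y = epochs.data[mask]
    if len(X) == 0:
        raise ValueError("no included trials")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)   # (n_reg, n_time)
    return {
        "coefficients": coef,
        "names": list(design.columns),
        "times_ms": epochs.times_ms,
        "n_trials": int(mask.sum()),
        "low_trial_count": bool(mask.sum() < min_trials),
    }


def binned_ttests(cohort_coefficients: np.ndarray, times_ms: np.ndarray,
                  names: list[str], bin_s: float = 1.0) -> pd.DataFrame:
    """Group one-sample t-tests on time-binned regression coefficients.

    ``cohort_coefficients`` is (n_participants, n_regressors,
    n_timepoints).  Each coefficient series is averaged within consecutive
    ``bin_s``-second bins; the per-bin participant means are tested against
    0.  Reported raw (no correction) with the bin count stated.
    """
    C = np.asarray(cohort_coefficients, float)
    n_part, n_reg, n_time = C.shape
    edges_ms = np.arange(0, times_ms[-1] + bin_s * 1000, bin_s * 1000)
    rows = []
    n_bins = len(edges_ms) - 1
    for r in range(n_reg):
        for bi in range(n_bins):
            in_bin = (times_ms >= edges_ms[bi]) & (times_ms < edges_ms[bi + 1])
            means = C[:, r, in_bin].mean(axis=1)
            if n_part <= 1:
                t, p = np.nan, np.nan      # df = 0: undefined, flagged as NaN
            elif np.allclose(means, 0.0):
                t, p = 0.0, 1.0            # identically zero coefficients
            else:
                t, p = stats.ttest_1samp(means, 0.0)
            rows.append({
                "regressor": names[r],
                "bin_start_s": edges_ms[bi] / 1000.0,
                "bin_end_s": edges_ms[bi + 1] / 1000.0,
                "mean": means.mean(),
                "t": float(t), "p": float(p),
                "df": n_part - 1,
                "n_bins": n_bins,
            })
    return pd.DataFrame(rows)
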