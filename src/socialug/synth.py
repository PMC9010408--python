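"""Synthetic cohorts with known ground truth.

Everything the analysis pipeline consumes can be generated here: Likert
rating tables (faces from the nonlinear weighting model, offers from the
liking regression, both plus rounding noise), closed-loop UG sessions in
which each synthetic responder's choices are drawn from their true
decision model through the task engine, participant covariates with
declared correlations to the true parameters, and 500 Hz pupil streams
built from known coefficient time-profiles plus AR(1) noise and blink
gaps.  A single master seed makes a cohort fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import task_engine
from .decision import get_model
from .inference import model_policy
from .perception import MU_CROSSOVER, LikingParams, WeightingParams, weighting_function
from .pupil import (BASELINE_S, DT_MS, RESPONSE_S, SAMPLING_HZ, DESIGN_COLUMNS,
                    PupilEpochs)

__all__ = [
    "CohortSpec",
    "Participant",
    "synth_ratings",
    "generate_cohort",
    "synth_sessions",
    "default_coef_profiles",
    "synth_epochs",
    "synth_pupil",
    "DEFAULT_LIKING_TRUTH",
]

#: liking-model truth on the Likert scale: ratings peak at the 50/50 split
#: (chi = 7 there) and stay mostly inside 1..9 to limit clipping saturation
DEFAULT_LIKING_TRUTH = LikingParams(phi0=5.0, phi1=0.004, phi2=-0.005)


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth world for a synthetic cohort.

    Defaults emulate the study's design (44 participants, 6 blocks of 40
    trials, 54 face and 100 offer ratings) in a regime where the emotion
    effect is expressed and the parameters are identifiable: perception
    delta ~ U[0.8, 1.6], gamma ~ U[0.5, 1.2]; parabolic inequality-model
    truth kappa ~ U[0.5, 2], omega ~ U[-4, -1] (pound scale), beta = 2 with
    +/-20% jitter.  ``svo_omega_corr`` couples social value orientation to
    the true inequality weight through a Gaussian copula (more prosocial
    -> more negative omega).
    """

    n_participants: int = 44
    model_id: int = 10
    n_blocks: int = 6
    trials_per_block: int = 40
    delta_range: tuple[float, float] = (0.8, 1.6)
    gamma_range: tuple[float, float] = (0.5, 1.2)
    kappa_range: tuple[float, float] = (0.5, 2.0)
    omega_range: tuple[float, float] = (-4.0, -1.0)
    beta_base: float = 2.0
    beta_jitter: float = 0.2
    rating_noise_sd: float = 0.5
    svo_omega_corr: float = -0.4
    liking_truth: LikingParams = DEFAULT_LIKING_TRUTH

    def identity_perception(self) -> "CohortSpec":
        """Variant whose responders perceive faces veridically (delta=gamma=1)."""
        return replace(self, delta_range=(1.0, 1.0), gamma_range=(1.0, 1.0))


@dataclass
class Participant:
    """One synthetic participant: truth, covariates, data."""

    pid: int
    truth: dict
    covariates: dict
    ratings: pd.DataFrame | None = None
    session: pd.DataFrame | None = None
    epsilons: np.ndarray | None = field(default=None, repr=False)


def synth_ratings(weighting: WeightingParams, liking: LikingParams,
                  noise_sd: float = 0.5, seed: int | np.random.Generator = 0,
                  n_face_reps: int = 6, n_offer_ratings: int = 100,
                  space: task_engine.StateSpace | None = None) -> pd.DataFrame:
    """Likert rating tables for faces (9 x 6 reps = 54) and offers (100).

    Face ratings: round(10 * epsilon(phi) + noise) clipped to 1..9.
    Offer ratings: round(chi(R_S, R_O) + noise) clipped to 1..9, offers
    drawn uniformly from the task's offer grid.
    """
    sp = space if space is not None else task_engine.make_state_space()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_face_reps + 1):
        for phi in sp.phi:
            eps = weighting_function(float(phi), weighting)
            likert = int(np.clip(np.round(10 * eps + rng.normal(0, noise_sd)), 1, 9))
            rows.append({"stimulus_type": "face", "phi": float(phi),
                         "R_S": np.nan, "R_O": np.nan,
                         "repetition": rep, "likert": likert})
    offers = rng.choice(sp.offers, size=n_offer_ratings, replace=True)
    for rep, rs in enumerate(offers, start=1):
        ro = sp.pot - int(rs)
        chi = liking.phi0 + liking.phi1 * rs + liking.phi2 * abs(rs - ro)
        likert = int(np.clip(np.round(chi + rng.normal(0, noise_sd)), 1, 9))
        rows.append({"stimulus_type": "offer", "phi": np.nan,
                     "R_S": int(rs), "R_O": ro,
                     "repetition": rep, "likert": likert})
    return pd.DataFrame(rows)


def _sample_truth(spec: CohortSpec, rng: np.random.Generator) -> tuple[dict, dict]:
    """One participant's true parameters and correlated covariates."""
    # Gaussian copula: couple omega to SVO at the declared correlation
    r = spec.svo_omega_corr
    z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]])
    u_omega = norm.cdf(z[0])
    lo, hi = spec.omega_range
    truth = {
        "delta": float(rng.uniform(*spec.delta_range)),
        "gamma": float(rng.uniform(*spec.gamma_range)),
        "kappa": float(rng.uniform(*spec.kappa_range)),
        "omega": float(lo + (hi - lo) * u_omega),
        "beta": float(spec.beta_base * rng.uniform(1 - spec.beta_jitter,
                                                   1 + spec.beta_jitter)),
    }
    covariates = {
        "mood": float(rng.normal(0, 2)),          # composite mood z-sum
        "svo": float(25 + 14 * z[1]),             # SVO slider angle
        "participant_sex": int(rng.random() < 0.68),
        "opponent_sex": int(rng.random() < 0.5),
        "opponent_type": int(rng.random() < 0.477),  # 1 = computerised
    }
    return truth, covariates


def generate_cohort(spec: CohortSpec = CohortSpec(), seed: int = 0,
                    with_ratings: bool = True) -> list[Participant]:
    """Sample a full cohort and play every session closed-loop.

    Each responder's policy draws choices Bernoulli(q) from their true
    decision model, with faces perceived through their true weighting
    function; the stimulus stream reacts through the default transition
    tables.  Deterministic for a fixed seed.
    """
    master = np.random.default_rng(seed)
    model = get_model(spec.model_id)
    out = []
    for pid in range(1, spec.n_participants + 1):
        truth, cov = _sample_truth(spec, master)
        weighting = WeightingParams(truth["delta"], truth["gamma"])
        params = {k: truth[k] for k in ("kappa", "omega", "beta")}
        policy = model_policy(model, params, weighting=weighting,
                              rng=np.random.default_rng(master.integers(2**31)))
        session = task_engine.run_session(
            policy,
            n_blocks=spec.n_blocks, trials_per_block=spec.trials_per_block,
            seed=np.random.default_rng(master.integers(2**31)))
        eps = weighting_function(session["phi"].to_numpy(float), weighting)
        ratings = (synth_ratings(weighting, spec.liking_truth,
                                 spec.rating_noise_sd,
                                 np.random.default_rng(master.integers(2**31)))
                   if with_ratings else None)
        out.append(Participant(pid=pid, truth=truth, covariates=cov,
                               ratings=ratings, session=session, epsilons=eps))
    return out


def synth_sessions(spec: CohortSpec = CohortSpec(), seed: int = 0) -> list[Participant]:
    """Cohort of closed-loop sessions only (no rating tables)."""
    return generate_cohort(spec, seed, with_ratings=False)


# --- pupil ground truth ---------------------------------------------------

def default_coef_profiles(times_ms: np.ndarray) -> dict[str, np.ndarray]:
    """True coefficient time courses for the pupillary design.

    The inequality regressor carries the signal of interest: a gamma-shaped
    response peaking inside the first post-offer second and decaying
    thereafter.  Every other regressor's true coefficient is zero.
    """
    t = np.asarray(times_ms, float) / 1000.0
    peak = 0.6
    profile = (t / peak) * np.exp(1.0 - t / peak)  # 1.0 at t = peak
    profiles = {name: np.zeros_like(t) for name in DESIGN_COLUMNS}
    profiles["inequality"] = 0.5 * profile
    return profiles


def synth_epochs(design: pd.DataFrame, profiles: dict[str, np.ndarray],
                 noise_sd: float = 0.0, seed: int = 0) -> PupilEpochs:
    """Epochs assembled directly from coefficient profiles (no raw stream).

    data[trial, t] = sum_k profiles[k][t] * design[k][trial] + white noise.
    Useful for identifiability checks of the time-point regression itself,
    bypassing preprocessing.
    """
    rng = np.random.default_rng(seed)
    n_time = len(next(iter(profiles.values())))
    times = np.arange(n_time) * DT_MS
    X = design.to_numpy(float)
    P = np.column_stack([profiles[name] for name in design.columns])  # (t, k)
    data = X @ P.T
    if noise_sd > 0:
        data = data + rng.normal(0, noise_sd, size=data.shape)
    n = len(design)
    return PupilEpochs(data=data, times_ms=times,
                       trials=np.arange(1, n + 1),
                       included=np.ones(n, dtype=bool),
                       interp_frac_outcome=np.zeros(n),
                       baseline_span_s=np.full(n, BASELINE_S))


def synth_pupil(design: pd.DataFrame,
                profiles: dict[str, np.ndarray] | None = None,
                noise_sd: float = 0.1, ar1: float = 0.97,
                blink_rate_hz: float = 0.1,
                seed: int = 0,
                trials: np.ndarray | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A raw 500 Hz pupil stream with events, from known regressor truth.

    Trial layout (12 s per trial): face onset at t0, offer at t0 + 7.5 s,
    decision at +9.5 s, outcome at +10.5 s, end at +12 s.  The response
    window carries the sum of profile x regressor products; AR(1) noise
    runs across the whole session; blinks arrive as a Poisson process with
    uniform 100-400 ms durations and flag samples invalid.
    """
    rng = np.random.default_rng(seed)
    n_resp = int(RESPONSE_S * SAMPLING_HZ)
    times = np.arange(n_resp) * DT_MS
    if profiles is None:
        profiles = default_coef_profiles(times)
    trial_s = BASELINE_S + RESPONSE_S
    n_trials = len(design)
    n_per_trial = int(trial_s * SAMPLING_HZ)
    n_total = n_trials * n_per_trial

    trial_ids = (np.asarray(trials, int) if trials is not None
                 else np.arange(1, n_trials + 1))
    X = design.to_numpy(float)
    P = np.column_stack([profiles[name] for name in design.columns])
    signal_part = np.zeros(n_total)
    events = []
    for i in range(n_trials):
        start = i * n_per_trial
        offer_idx = start + int(BASELINE_S * SAMPLING_HZ)
        signal_part[offer_idx:offer_idx + n_resp] = P @ X[i]
        t0_ms = start * DT_MS
        trial = int(trial_ids[i])
        events += [
            {"trial": trial, "event_name": "trial_start", "time_ms": t0_ms},
            {"trial": trial, "event_name": "face_onset", "time_ms": t0_ms},
            {"trial": trial, "event_name": "offer_onset", "time_ms": offer_idx * DT_MS},
            {"trial": trial, "event_name": "decision", "time_ms": t0_ms + 9500},
            {"trial": trial, "event_name": "outcome", "time_ms": t0_ms + 10500},
        ]

    if noise_sd > 0:
        innov = rng.normal(0, noise_sd * np.sqrt(1 - ar1 ** 2), size=n_total)
        noise = np.empty(n_total)
        noise[0] = rng.normal(0, noise_sd)
        for i in range(1, n_total):
            noise[i] = ar1 * noise[i - 1] + innov[i]
    else:
        noise = np.zeros(n_total)

    valid = np.ones(n_total, dtype=int)
    if blink_rate_hz > 0:
        duration_s = n_total / SAMPLING_HZ
        n_blinks = rng.poisson(blink_rate_hz * duration_s)
        for _ in range(n_blinks):
            start = rng.integers(0, n_total)
            length = int(rng.uniform(0.1, 0.4) * SAMPLING_HZ)
            valid[start:start + length] = 0

    samples = pd.DataFrame({
        "time_ms": np.arange(n_total) * DT_MS,
        "pupil": signal_part + noise,
        "valid": valid,
    })
    return samples, pd.DataFrame(events)
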