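"""End-to-end orchestration of the synthetic study.

``run_pipeline`` reproduces the whole analysis on a generated cohort:
simulate closed-loop sessions, fit the rating models, fit and compare the
choice models, run the model-free behavioural statistics and (optionally)
the pupillary pipeline on a subset of participants.  One seed controls
everything; with an output directory the artefacts are written as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour, filtering, inference, io, pupil, synth
from .decision import get_model
from .perception import fit_liking, fit_weighting, weighting_function

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full synthetic run."""

    n_participants: int = 8
    n_blocks: int = 6
    trials_per_block: int = 40
    model_ids: tuple[int, ...] = (4, 10)
    grid_points: int = 21
    seed: int = 0
    pupil_participants: int = 0      # 0 disables the pupil stage
    pupil_trials: int = 40
    out_dir: str | None = None

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        if self.grid_points < 2:
            raise ValueError("grid_points must be at least 2")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "model_ids" in d:
            d = {**d, "model_ids": tuple(d["model_ids"])}
        return cls(**d)


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run simulate -> fit-ratings -> fit -> select -> analyse [-> pupil]."""
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_dict(config)
    spec = synth.CohortSpec(n_participants=cfg.n_participants,
                            n_blocks=cfg.n_blocks,
                            trials_per_block=cfg.trials_per_block)
    cohort = synth.generate_cohort(spec, seed=cfg.seed)

    # stage 1: rating models per participant
    rating_fits = []
    for p in cohort:
        faces = p.ratings[p.ratings["stimulus_type"] == "face"]
        offers = p.ratings[p.ratings["stimulus_type"] == "offer"]
        wfit = fit_weighting(faces)
        lik = fit_liking(offers)
        rating_fits.append({"weighting": wfit["params"], "liking": lik})

    # stage 2: choice-model fits (model 4 first, as the stage-1 template
    # whose estimates feed the weighted-integration model)
    ids = list(cfg.model_ids)
    if 11 in ids and 4 not in ids:
        ids = [4] + ids
    ids = sorted(set(ids), key=lambda m: (m != 4, m))
    fits: dict[int, list] = {m: [] for m in ids}
    for i, p in enumerate(cohort):
        eps = weighting_function(p.session["phi"].to_numpy(float),
                                 rating_fits[i]["weighting"])
        context: dict = {"liking": rating_fits[i]["liking"]}
        for m in ids:
            fit = inference.fit_model(get_model(m), p.session, eps,
                                      context=context,
                                      grid_points=cfg.grid_points,
                                      store_posterior=False)
            fits[m].append(fit)
            if m == 4:
                context["base"] = {"kappa": fit.params["kappa"],
                                   "omega": fit.params["omega"]}

    selection = (inference.select_models({m: fits[m] for m in cfg.model_ids},
                                         seed=cfg.seed)
                 if len(cfg.model_ids) > 1 else None)

    # stage 3: model-free behavioural statistics
    sessions = [p.session for p in cohort]
    grids = [behaviour.acceptance_grid(s) for s in sessions]
    main_effects = behaviour.main_effects_ols(grids)
    history = behaviour.history_logistic_cohort(sessions)
    expected = np.array([behaviour.expected_outcome(s) for s in sessions])
    best_id = max(cfg.model_ids,
                  key=lambda m: np.mean([f.accuracy for f in fits[m]]))
    covariates = pd.DataFrame([p.covariates for p in cohort])
    omega_hat = np.array([f.params.get("omega", np.nan) for f in fits[best_id]])
    param_cov = (behaviour.parameter_covariates_ols(omega_hat, covariates)
                 if cfg.n_participants > len(covariates.columns) + 1 else None)

    # stage 4: pupil pipeline on a participant subset
    pupil_report = None
    if cfg.pupil_participants > 0:
        coef_stack = []
        rng = np.random.default_rng(cfg.seed + 1)
        for i, p in enumerate(cohort[:cfg.pupil_participants]):
            sess = p.session.iloc[:cfg.pupil_trials]
            regs = filtering.session_filter_regressors(sess)
            fit = fits[best_id][i]
            design = pupil.build_design(
                sess, {"kappa": fit.params.get("kappa", 1.0),
                       "omega": fit.params.get("omega", -1.0)},
                regs, epsilons=p.epsilons[:cfg.pupil_trials])
            samples, events = synth.synth_pupil(
                design, noise_sd=0.1, blink_rate_hz=0.1,
                seed=int(rng.integers(2**31)),
                trials=sess["trial"].to_numpy())
            epochs = pupil.preprocess(samples, events,
                                      session_trials=sess["trial"].to_numpy())
            reg = pupil.timepoint_regression(epochs, design)
            coef_stack.append(reg["coefficients"])
        coef_stack = np.array(coef_stack)
        pupil_report = {
            "coefficients": coef_stack,
            "names": pupil.DESIGN_COLUMNS,
            "binned": pupil.binned_ttests(coef_stack,
                                          np.arange(coef_stack.shape[2]) * pupil.DT_MS,
                                          pupil.DESIGN_COLUMNS),
        }

    report = {
        "config": asdict(cfg),
        "cohort": cohort,
        "rating_fits": rating_fits,
        "fits": fits,
        "selection": selection,
        "main_effects": main_effects,
        "history": history,
        "expected_outcome": expected,
        "parameter_covariates": param_cov,
        "pupil": pupil_report,
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for p in cohort:
            io.write_session(p.session, out / f"session_{p.pid:02d}.csv")
            if p.ratings is not None:
                io.write_ratings(p.ratings, out / f"ratings_{p.pid:02d}.csv")
        main_effects["group"].to_csv(out / "main_effects.csv", index=False)
        history["group"].to_csv(out / "history_logistic.csv", index=False)
        if selection is not None:
            pd.DataFrame({
                "model_id": selection["model_ids"],
                "summed_bic": [selection["summed_bic"][m] for m in selection["model_ids"]],
                "expected_freq": [selection["expected_freq"][m] for m in selection["model_ids"]],
                "exceedance": [selection["exceedance"][m] for m in selection["model_ids"]],
            }).to_csv(out / "model_selection.csv", index=False)
    return report
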