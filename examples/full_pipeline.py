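"""One-call reproduction of the whole synthetic study.

Simulates a small cohort, fits the rating models, fits and compares two
choice models, runs the behavioural statistics and the pupil stage for
two participants.
"""

from socialug.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(
    n_participants=6, model_ids=(4, 10), grid_points=21, seed=0,
    pupil_participants=2, pupil_trials=40))

sel = report["selection"]
print("model selection (summed BIC):",
      {m: round(b, 1) for m, b in sel["summed_bic"].items()})
print("exceedance:", {m: round(x, 3) for m, x in sel["exceedance"].items()})

best = sel["best_bic"]
accs = [f.accuracy for f in report["fits"][best]]
print(f"best model {best}: mean predictive accuracy "
      f"{sum(accs) / len(accs):.3f}")

main = report["main_effects"]["group"].set_index("regressor")
print("offer main effect: t = %.2f" % main.loc["offer", "t"])
if report["pupil"] is not None:
    print("pupil stage: coefficient series shape",
          report["pupil"]["coefficients"].shape)
# End to end, the synthetic study reproduces the analysis chain from raw
# stimuli to model selection and pupillary coefficients with one seed.
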