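"""Time-resolved pupillary regression with known ground truth.

A 500 Hz pupil stream is synthesised from an injected inequality response
(peaking 600 ms after offer onset), preprocessed (blink interpolation,
3.75 Hz low-pass, z-transform, baseline correction), and regressed at
every 2-ms time point on the 11-column trial-wise design.
"""

import numpy as np

from socialug import filtering, pupil
from socialug.synth import CohortSpec, default_coef_profiles, synth_pupil, synth_sessions

participant = synth_sessions(
    CohortSpec(n_participants=1, n_blocks=1, trials_per_block=40).identity_perception(),
    seed=5)[0]
session = participant.session

regressors = filtering.session_filter_regressors(session)
design = pupil.build_design(session,
                            {"kappa": participant.truth["kappa"],
                             "omega": participant.truth["omega"]},
                            regressors, epsilons=participant.epsilons)

profiles = default_coef_profiles(np.arange(2250) * pupil.DT_MS)
samples, events = synth_pupil(design, profiles, noise_sd=0.05,
                              blink_rate_hz=0.1, seed=5,
                              trials=session["trial"].to_numpy())
print(f"raw stream: {len(samples)} samples "
      f"({len(samples) / 500 / 60:.1f} min at 500 Hz)")

epochs = pupil.preprocess(samples, events,
                          session_trials=session["trial"].to_numpy())
print(f"included trials: {epochs.n_included}/{len(session)} "
      f"(excluded if >50% of the outcome window was interpolated)")

out = pupil.timepoint_regression(epochs, design)
i = out["names"].index("inequality")
recovered = out["coefficients"][i] * epochs.z_sd
peak = out["times_ms"][np.argmax(recovered)]
print(f"inequality coefficient peaks at {peak} ms "
      f"(injected peak 600 ms), amplitude {recovered.max():.2f} "
      f"(injected 0.50)")
# The regression recovers the injected first-second inequality response:
# pupil size tracks the magnitude of self-other inequality before the
# decision.
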