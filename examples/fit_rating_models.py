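"""Fit the perception models to synthetic Likert ratings.

Face ratings follow the two-parameter weighting function
epsilon = exp(-delta(-ln phi)^gamma); offer ratings follow the liking
regression chi = phi0 + phi1*R_S + phi2*|R_S - R_O|.  Both are generated
from known truth plus rounding noise and then recovered.
"""

from socialug.perception import LikingParams, WeightingParams, fit_liking, fit_weighting
from socialug.synth import synth_ratings

truth_w = WeightingParams(delta=1.3, gamma=0.7)
truth_l = LikingParams(phi0=5.0, phi1=0.004, phi2=-0.005)
ratings = synth_ratings(truth_w, truth_l, noise_sd=0.5, seed=3)

faces = ratings[ratings["stimulus_type"] == "face"]
offers = ratings[ratings["stimulus_type"] == "offer"]
print(f"{len(faces)} face ratings, {len(offers)} offer ratings")

west = fit_weighting(faces)["params"]
print(f"weighting truth (delta, gamma) = ({truth_w.delta}, {truth_w.gamma}); "
      f"fitted = ({west.delta:.3f}, {west.gamma:.3f})")

lest = fit_liking(offers)
print(f"liking truth (phi0, phi1, phi2) = (5.0, 0.004, -0.005); "
      f"fitted = ({lest.phi0:.2f}, {lest.phi1:.5f}, {lest.phi2:.5f})")
# A negative phi2 means the rater dislikes unequal splits; gamma < 1 bends
# perceived valence so negative faces are discriminated more coarsely.
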