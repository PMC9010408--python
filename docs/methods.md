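# Methods

This note records the models, numerical choices and known limitations of
the package, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Task model

The proposer is a Markov strategy over two independent streams. Each
stream (face index 1..9, offer index 1..19) moves by at most one step per
trial; the move distribution depends only on the responder's last choice.
Default tables (loadable/overridable as plain data):

| response | face (-1, stay, +1) | offer (-1, stay, +1) |
|----------|--------------------|----------------------|
| accept   | 0.10, 0.30, 0.60   | 0.50, 0.35, 0.15     |
| reject   | 0.60, 0.30, 0.10   | 0.15, 0.35, 0.50     |

These encode the qualitative proposer strategy (happier after accepts,
angrier after rejects; offers probe the acceptance threshold). At a grid
boundary the out-of-range mass is dropped and the row renormalised
(clamp-and-renormalise), preserving relative stay/step odds. Blocks are
independent restarts at (neutral face, 500p); the post-decision reaction
face becomes the next trial's pre-offer face within a block. One numpy
`Generator` seeded per session drives all draws sequentially, so a
session is a pure function of (seed, config, policy).

## Perception

Face ratings (Likert 1..9, divided by 10) are fit with the Prelec-form
weighting function `eps = exp(-delta(-ln phi)^gamma)` by bounded
least squares on the log-parameter scale, multi-started from a 5x5
log-spaced lattice over (0.01, 5], convergence tolerance 1e-9; the
best-of-starts solution is kept, and all 54 ratings enter jointly. The
crossover constant mu = 0.4 is a fixed module constant; per-trial
epsilons come from each participant's own fitted (delta, gamma). Offer
ratings are fit by OLS on the raw Likert scale (only face ratings need
the unit interval, to share the weighting function's range); R_O never
enters separately because the pot is fixed.

## Decision models and fitting

Offers are rescaled from pence to pounds before any value function, so
softmax temperatures are well-conditioned; the fairness threshold lambda
is estimated in pence (50..950) and converted internally. Parameter grids
(defaults, 41 nodes each): weights kappa, omega in [0, 10] (exponential
bases log-spaced in [0.1, 10]); parabolic-variant omega in [-10, 10]
(the printed "+omega" convention with omega allowed negative, so aversion
is omega < 0 and emotion relaxes it); integration weight w in [0, 1];
beta log-spaced in [0.01, 20]. A probability floor of 1e-10 is applied to
q and 1-q before logs. The posterior is exp(lnL) times a uniform grid
prior; point estimates are posterior means; predicted choice is accept
iff q >= 0.5 (ties accept); accuracy is in-sample at the posterior-mean
parameters. BIC uses the grid maximum of lnL and k = free parameters
including beta. For the weighted-integration model, the plugged-in
(kappa, omega) come from the stage-1 inequality-model fit *to the same
session* and are therefore counted in k (k = 4): with k = 2 the model
inherits the stage-1 fit at w = 1 while paying for two parameters and
degenerately wins every comparison. Random-effects model selection uses
-BIC/2 as approximate log evidence in the standard variational Dirichlet
scheme; exceedance probabilities are Monte-Carlo estimates (1e5 seeded
Dirichlet draws).

Single-term exponential variants estimate the unmodulated weight as a
free linear parameter rather than pinning it at 1.

## Bayesian filter

A deliberate reconstruction, used only to build nuisance regressors: the
latent mean performs a Gaussian random walk with step SD = volatility;
observations are mean + Gaussian noise; volatility and noise are static
nodes of a joint grid (61 mean nodes spanning the observation range
±20%, 21 log-spaced volatility nodes in [0.005, 0.5] x range, 21
log-spaced noise nodes in [0.01, 1] x range). Each trial runs
predict (per-volatility diffusion kernel, columns normalised) →
surprise (negative log of the grid-marginal mixture predictive density,
not a single-node plug-in) → Bayes update. Offers are standardised to
pounds and faces filtered on (0, 1) so one grid construction serves both
streams.

## Pupillometry

Invalid samples are linearly interpolated; the trace is filtered with a
3rd-order Butterworth low-pass at 3.75 Hz applied forward–backward
(zero-phase, preserving event latencies), then z-transformed across the
session (the absorbed mean/SD are kept on the epochs so coefficients can
be mapped back to raw units). Epochs: 7.5 s pre-offer baseline (shorter
spans are used and recorded when a trial starts late), 4.5 s response
window (2,250 points at 2 ms); baseline-mean subtraction per trial;
exclusion when more than 50% of a 1.5 s outcome window was interpolated.
The 11-regressor design (constant; trial index; kappa*R_S; omega +
(eps-mu)^2; |R_S-R_O|; surprise/volatility/noise for offers and faces) is
demeaned except the constant, fit independently at every time point by
OLS across included trials (fewer than 10 trials is flagged), and group
inference bins coefficients at 1 s with one-sample t-tests, reported raw
with the bin count stated (regressors within a multiple regression
compete for variance and are not further corrected).

## Synthetic world

Cohort defaults state the emulated study design: 44 participants, 6x40
trials, 54 face + 100 offer ratings. Truth samplers: delta ~ U[0.8, 1.6],
gamma ~ U[0.5, 1.2]; model-10 truth kappa ~ U[0.5, 2], omega ~ U[-4, -1]
(pound scale), beta = 2 ± 20%. Covariates couple to truth through a
Gaussian copula (SVO–omega correlation -0.4, more prosocial → more
negative omega). The liking truth (5.0, 0.004, -0.005 on the Likert
scale) peaks at the 50/50 split while keeping most ratings inside 1..9,
limiting clipping saturation. Pupil truth: an inequality coefficient
profile `0.5 * (t/0.6s) * exp(1 - t/0.6s)` peaking inside the first
post-offer second, zero truth for all other regressors, AR(1) noise
(phi = 0.97) and Poisson blinks (0.1/s, 100–400 ms). The generators do
not emulate real-data features such as luminance artefacts, saccades,
non-stationary preferences or learning, so a green test establishes
pipeline correctness under the stated world, not behavioural realism.

## Known identifiability limits

Two properties of the 240-trial adaptive design were measured during
development and are asserted (and currently failing, by design honestly
reported) in the acceptance suite:

1. **Scale ridge.** Rescaling (kappa, omega) by c and beta by 1/c changes
   the likelihood only through the additive (eps-mu)^2 term; at the
   stated truth regime the log-likelihood varies by only a few nats along
   an 8-fold rescaling. Posterior means over the wide uniform grids are
   therefore volume-biased toward larger weights and smaller beta, and
   generate–recover correlations for omega and beta stay well below the
   0.8 stability bar. Predictive accuracy is insensitive to the ridge
   (the choice rule depends mostly on the value's sign).
2. **Modulated-term ambiguity.** Visited offers are predominantly
   disadvantageous, where |R_S - R_O| = 10 - 2*R_S, so the parabolic
   modulation applied to the self term versus the inequality term spans
   nearly the same regressor space; models 8, 9 and 10 differ by ~0.1
   nats per participant on model-10 data. The *presence* of the emotion
   effect is decisively detected (all parabolic variants beat the
   emotion-free model by a large BIC margin), but not *which* term it
   acts on.

## Degenerate inputs and tie-breaks

Constant face ratings are flagged and fit at the boundary with a warning;
constant pupil traces z-transform to zeros with a warning; logistic
separation falls back to a small ridge penalty (1e-4) with a warning;
q = 0.5 ties predict accept; all-zero binned coefficients report t = 0,
p = 1, and single-participant cohorts report NaN with df = 0.
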