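"""Candidate decision-value models for the responder in the iterative UG.

Eleven value functions compete to explain accept/reject choices.  Writing
R_S for the responder's share, R_O for the proposer's share and
D = |R_S - R_O| for the inequality magnitude (all rescaled from pence to
pounds before entering a value function, so the softmax temperature is
well-conditioned):

 1. CES               v = (a*R_S^rho + (1-a)*D^rho)^(1/rho)
 2. fairness threshold v = lambda - D
 3. liking            v = chi(R_S, R_O) from the rater's own liking model
 4. inequality aversion v = kappa*R_S - omega*D
 5-7. exponential emotion modulation, v with kappa and/or omega replaced by
      kappa^(eps-mu), omega^(eps-mu)  (eps = perceived facial valence,
      mu = 0.4 the perceptual crossover)
 8-10. parabolic emotion modulation, base weights shifted by +(eps-mu)^2;
      model 10 (the best-fitting model) modulates the inequality term only:
      v = kappa*R_S + (omega + (eps-mu)^2)*D with omega typically negative
 11. weighted integration v = w*v_ineq + (1-w)*(eps-mu)

Choices follow a softmax q_accept = 1 / (1 + exp(-beta * v)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.special import expit

from .perception import MU_CROSSOVER, LikingParams

__all__ = [
    "GridSpec",
    "DecisionModelSpec",
    "value_ces",
    "value_threshold",
    "value_liking",
    "value_inequality",
    "value_emotion_exp",
    "value_emotion_parabolic",
    "value_weighted_integration",
    "accept_probability",
    "predict_choice",
    "model_registry",
    "get_model",
    "trial_values",
]

PENCE_PER_POUND = 100.0


# --- value functions (unit-agnostic, vectorised) --------------------------

def value_ces(R_S, R_O, alpha, rho):
    """Constant-elasticity-of-substitution aggregate of reward and inequality."""
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr == 0):
        raise ValueError("rho = 0 not supported (log-limit not implemented)")
    R_S, R_O = np.asarray(R_S, dtype=float), np.asarray(R_O, dtype=float)
    d = np.abs(R_S - R_O)
    return (alpha * R_S ** rho + (1.0 - alpha) * d ** rho) ** (1.0 / rho)


def value_threshold(R_S, R_O, lam):
    """Inequality compared against a subjective fairness threshold."""
    return lam - np.abs(np.asarray(R_S, float) - np.asarray(R_O, float))


def value_liking(R_S, R_O, liking: LikingParams):
    """Decision value equal to the predicted liking rating chi."""
    d = np.abs(np.asarray(R_S, float) - np.asarray(R_O, float))
    return liking.phi0 + liking.phi1 * np.asarray(R_S, float) + liking.phi2 * d


def value_inequality(R_S, R_O, kappa, omega):
    """Fehr-Schmidt-style inequality aversion with a single aversion weight."""
    d = np.abs(np.asarray(R_S, float) - np.asarray(R_O, float))
    return kappa * np.asarray(R_S, float) - omega * d


def value_emotion_exp(R_S, R_O, epsilon, kappa, omega, mu=MU_CROSSOVER,
                      variant="both"):
    """Exponential emotion modulation of the base weights.

    A modulated weight x becomes x**(epsilon - mu): neutral faces
    (epsilon = mu) leave it at 1, positive faces amplify weights > 1 and
    shrink weights < 1.  ``variant`` selects which term is modulated; the
    unmodulated term keeps its weight as a plain linear multiplier.
    """
    R_S = np.asarray(R_S, float)
    d = np.abs(R_S - np.asarray(R_O, float))
    e = np.asarray(epsilon, float) - mu
    kappa = np.asarray(kappa, float)
    omega = np.asarray(omega, float)
    if variant in ("self", "both") and np.any(kappa <= 0):
        raise ValueError("modulated kappa must be positive")
    if variant in ("inequality", "both") and np.any(omega <= 0):
        raise ValueError("modulated omega must be positive")
    if variant == "self":
        return kappa ** e * R_S - omega * d
    if variant == "inequality":
        return kappa * R_S - omega ** e * d
    if variant == "both":
        return kappa ** e * R_S - omega ** e * d
    raise ValueError(f"unknown variant {variant!r}")


def value_emotion_parabolic(R_S, R_O, epsilon, kappa, omega, mu=MU_CROSSOVER,
                            variant="inequality"):
    """Parabolic emotion modulation: weights shifted by +(epsilon - mu)^2.

    Increasingly positive *or* negative faces act alike; a neutral face
    (epsilon = mu) contributes nothing.  With the inequality-only variant
    (the best-fitting model) and a negative base omega, affective load
    relaxes the negative valuation of inequality.
    """
    R_S = np.asarray(R_S, float)
    d = np.abs(R_S - np.asarray(R_O, float))
    p = (np.asarray(epsilon, float) - mu) ** 2
    if variant == "self":
        return (kappa + p) * R_S + omega * d
    if variant == "inequality":
        return kappa * R_S + (omega + p) * d
    if variant == "both":
        return (kappa + p) * R_S + (omega + p) * d
    raise ValueError(f"unknown variant {variant!r}")


def value_weighted_integration(v_base, epsilon, mu=MU_CROSSOVER, w=0.5):
    """Convex mix of a monetary decision value and the affect value."""
    return w * np.asarray(v_base, float) + (1.0 - w) * (np.asarray(epsilon, float) - mu)


def accept_probability(v, beta):
    """Softmax acceptance probability q = 1 / (1 + exp(-beta * v))."""
    z = np.asarray(beta, float) * np.asarray(v, float)
    out = expit(z)
    return float(out) if np.isscalar(v) and np.isscalar(beta) else out


def predict_choice(v, beta):
    """Deterministic choice rule: accept iff q_accept >= 0.5 (tie -> accept)."""
    q = accept_probability(v, beta)
    return (np.asarray(q) >= 0.5).astype(int)


# --- model registry -------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Bounds and spacing of one parameter's estimation grid."""

    low: float
    high: float
    spacing: str = "linear"  # or "log"

    def nodes(self, n: int) -> np.ndarray:
        if self.spacing == "log":
            return np.geomspace(self.low, self.high, n)
        return np.linspace(self.low, self.high, n)


#: softmax inverse temperature, shared by every model (pound scale)
BETA_GRID = GridSpec(0.01, 20.0, "log")


@dataclass(frozen=True)
class DecisionModelSpec:
    """One candidate model: id, variant tag, parameters and value function.

    ``value_fn(R_S, R_O, epsilon, params, context)`` returns decision values
    with full numpy broadcasting over the parameter axes; R_S/R_O arrive in
    pounds.  ``requires`` names context entries the model needs (fitted
    liking coefficients, or the stage-1 inequality-model parameters).
    """

    id: int
    name: str
    params: Mapping[str, GridSpec]     # free parameters excluding beta
    value_fn: Callable
    requires: tuple[str, ...] = ()
    #: parameters consumed from an earlier fit to the *same* session (the
    #: integration model's plugged-in kappa, omega); counted in BIC's k so a
    #: model cannot launder complexity through a pre-fit
    extra_k: int = 0

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(self.params) + ("beta",)

    @property
    def k(self) -> int:
        """Effective parameter count: grid parameters, beta, and any
        plug-ins estimated from the same data in an earlier stage."""
        return len(self.params) + 1 + self.extra_k

    def values(self, R_S, R_O, epsilon, params: Mapping, context: Mapping | None = None):
        return self.value_fn(R_S, R_O, epsilon, params, context or {})


def _v_ces(R_S, R_O, eps, p, ctx):
    return value_ces(R_S, R_O, p["alpha"], p["rho"])


def _v_threshold(R_S, R_O, eps, p, ctx):
    # lambda is estimated in pence (50..950) but values are computed in pounds
    return value_threshold(R_S, R_O, p["lam"] / PENCE_PER_POUND)


def _v_liking(R_S, R_O, eps, p, ctx):
    liking = ctx["liking"]
    return value_liking(R_S * PENCE_PER_POUND, R_O * PENCE_PER_POUND, liking)


def _v_inequality(R_S, R_O, eps, p, ctx):
    return value_inequality(R_S, R_O, p["kappa"], p["omega"])


def _v_exp(variant):
    def fn(R_S, R_O, eps, p, ctx):
        return value_emotion_exp(R_S, R_O, eps, p["kappa"], p["omega"],
                                 variant=variant)
    return fn


def _v_parab(variant):
    def fn(R_S, R_O, eps, p, ctx):
        return value_emotion_parabolic(R_S, R_O, eps, p["kappa"], p["omega"],
                                       variant=variant)
    return fn


def _v_weighted(R_S, R_O, eps, p, ctx):
    base = ctx["base"]  # posterior-mean (kappa, omega) of the stage-1 winner
    v0 = value_inequality(R_S, R_O, base["kappa"], base["omega"])
    return value_weighted_integration(v0, eps, w=p["w"])


_LIN_POS = GridSpec(0.0, 10.0)
_LOG_POS = GridSpec(0.1, 10.0, "log")
_LIN_SYM = GridSpec(-10.0, 10.0)


def model_registry() -> list[DecisionModelSpec]:
    """The 11 candidate models, ordered by id.

    Only a few ids are pinned by convention (model 10 is the parabolic
    inequality-only model); the list is plain data, so custom registries
    with remapped ids are just alternative lists.
    """
    return [
        DecisionModelSpec(1, "ces",
                          {"alpha": GridSpec(0.0, 1.0), "rho": GridSpec(0.2, 2.0)},
                          _v_ces),
        DecisionModelSpec(2, "threshold",
                          {"lam": GridSpec(50.0, 950.0)}, _v_threshold),
        DecisionModelSpec(3, "liking", {}, _v_liking, requires=("liking",)),
        DecisionModelSpec(4, "inequality",
                          {"kappa": _LIN_POS, "omega": _LIN_POS}, _v_inequality),
        DecisionModelSpec(5, "exp-self",
                          {"kappa": _LOG_POS, "omega": _LIN_POS}, _v_exp("self")),
        DecisionModelSpec(6, "exp-inequality",
                          {"kappa": _LIN_POS, "omega": _LOG_POS},
                          _v_exp("inequality")),
        DecisionModelSpec(7, "exp-both",
                          {"kappa": _LOG_POS, "omega": _LOG_POS}, _v_exp("both")),
        DecisionModelSpec(8, "parabolic-self",
                          {"kappa": _LIN_POS, "omega": _LIN_SYM}, _v_parab("self")),
        DecisionModelSpec(9, "parabolic-both",
                          {"kappa": _LIN_POS, "omega": _LIN_SYM}, _v_parab("both")),
        DecisionModelSpec(10, "parabolic-inequality",
                          {"kappa": _LIN_POS, "omega": _LIN_SYM},
                          _v_parab("inequality")),
        DecisionModelSpec(11, "weighted-integration",
                          {"w": GridSpec(0.0, 1.0)}, _v_weighted,
                          requires=("base",), extra_k=2),
    ]


def get_model(model_id: int) -> DecisionModelSpec:
    for spec in model_registry():
        if spec.id == model_id:
            return spec
    raise KeyError(f"no model with id {model_id}")


def trial_values(spec: DecisionModelSpec, session, epsilons, params: Mapping,
                 context: Mapping | None = None) -> np.ndarray:
    """Per-trial decision values for one parameter setting.

    ``session`` is a session table (offers in pence; converted to pounds
    here); ``epsilons`` the per-trial perceived valences.
    """
    R_S = session["offer_pence"].to_numpy(float) / PENCE_PER_POUND
    R_O = session["other_pence"].to_numpy(float) / PENCE_PER_POUND
    eps = np.asarray(epsilons, float)
    return np.asarray(spec.values(R_S, R_O, eps, params, context), float)
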