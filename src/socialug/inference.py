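"""Grid-based Bayesian estimation and model selection for choice models.

Each candidate model is fit to one responder's choices by evaluating the
Bernoulli log-likelihood of the observed accept/reject sequence on an
exhaustive Cartesian grid over the model's parameters (a uniform prior over
the grid).  Point estimates are posterior means — the posterior-weighted
integral of the node values — rather than the MAP node.  Models are
compared by group-summed BIC and by random-effects Bayesian model
selection, treating -BIC/2 as an approximate log model evidence and
estimating expected model frequencies and exceedance probabilities under
the variational Dirichlet scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma
from scipy.stats import pearsonr

from . import task_engine
from .decision import (DecisionModelSpec, BETA_GRID, PENCE_PER_POUND,
                       accept_probability, get_model, trial_values)

__all__ = [
    "ParameterGrid",
    "FitResult",
    "build_grid",
    "grid_log_likelihood",
    "fit_model",
    "bic",
    "predictive_accuracy",
    "select_models",
    "generate_recover",
    "model_policy",
]

#: floor applied to q and 1-q before taking logs (grid extremes otherwise
#: produce -inf and poison the posterior)
PROB_FLOOR = 1e-10

#: default number of grid nodes per parameter
DEFAULT_GRID_POINTS = 41


@dataclass(frozen=True)
class ParameterGrid:
    """Cartesian estimation grid: node values per parameter, in axis order."""

    names: tuple[str, ...]
    nodes: tuple[np.ndarray, ...]

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(n) for n in self.nodes)

    def axis_view(self, i: int, extra_axes: int = 0) -> np.ndarray:
        """Node array of parameter ``i`` shaped to broadcast over the grid."""
        shape = [1] * (len(self.nodes) + extra_axes)
        shape[extra_axes + i] = len(self.nodes[i])
        return self.nodes[i].reshape(shape)


def build_grid(spec: DecisionModelSpec, grid_points: int = DEFAULT_GRID_POINTS,
               beta_points: int | None = None) -> ParameterGrid:
    """Estimation grid for a model: its own parameters, then beta (last axis)."""
    names, nodes = [], []
    for name, gs in spec.params.items():
        names.append(name)
        nodes.append(gs.nodes(grid_points))
    names.append("beta")
    nodes.append(BETA_GRID.nodes(beta_points or grid_points))
    return ParameterGrid(names=tuple(names), nodes=tuple(nodes))


def _grid_values(spec: DecisionModelSpec, session: pd.DataFrame,
                 epsilons: np.ndarray, grid: ParameterGrid,
                 context: Mapping | None) -> np.ndarray:
    """Decision values, shape (n_trials, *non-beta grid axes)."""
    n_free = len(grid.names) - 1  # beta handled outside the value function
    R_S = session["offer_pence"].to_numpy(float) / PENCE_PER_POUND
    R_O = session["other_pence"].to_numpy(float) / PENCE_PER_POUND
    eps = np.asarray(epsilons, float)
    tshape = (-1,) + (1,) * n_free
    params = {
        name: grid.nodes[i].reshape((1,) * (1 + i) + (-1,) + (1,) * (n_free - 1 - i))
        for i, name in enumerate(grid.names[:-1])
    }
    # reshape trial vectors to broadcast against the parameter axes
    v = spec.values(R_S.reshape(tshape), R_O.reshape(tshape),
                    eps.reshape(tshape), params, context or {})
    return np.broadcast_to(np.asarray(v, float),
                           (len(R_S),) + grid.shape[:-1]).copy()


def grid_log_likelihood(spec: DecisionModelSpec, session: pd.DataFrame,
                        epsilons: np.ndarray,
                        grid: ParameterGrid | None = None,
                        context: Mapping | None = None,
                        beta_chunk: int = 8) -> tuple[np.ndarray, ParameterGrid]:
    """Bernoulli log-likelihood of the choices at every grid node.

    Returns an array with one axis per parameter (beta last).  Computed in
    beta-chunks to bound peak memory on large grids.
    """
    if len(session) == 0:
        raise ValueError("empty session")
    choices = session["choice"].to_numpy(float)
    if grid is None:
        grid = build_grid(spec)
    v = _grid_values(spec, session, epsilons, grid, context)  # (T, *free)
    betas = grid.nodes[-1]
    log_floor = np.log(PROB_FLOOR)
    out = np.empty(grid.shape, dtype=float)
    c = choices.reshape((-1,) + (1,) * (v.ndim - 1) + (1,))
    for start in range(0, len(betas), beta_chunk):
        b = betas[start:start + beta_chunk]
        z = v[..., None] * b  # (T, *free, nb)
        # log q = -log1p(exp(-z)); log(1-q) = -z + log q
        log_q = -np.logaddexp(0.0, -z)
        log_1mq = -z + log_q
        np.clip(log_q, log_floor, None, out=log_q)
        np.clip(log_1mq, log_floor, None, out=log_1mq)
        out[..., start:start + len(b)] = (c * log_q + (1.0 - c) * log_1mq).sum(axis=0)
    return out, grid


def bic(max_loglik: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, k*ln(n) - 2*lnL; lower is better."""
    return k * np.log(n) - 2.0 * max_loglik


@dataclass
class FitResult:
    """Grid-posterior fit of one model to one responder's session."""

    model_id: int
    model_name: str
    params: dict[str, float]          # posterior means
    max_loglik: float
    bic: float
    accuracy: float                   # fraction of choices matched at q>=0.5
    n_trials: int
    q_accept: np.ndarray = field(repr=False)          # trial-wise q at estimates
    posterior: np.ndarray | None = field(default=None, repr=False)
    grid: ParameterGrid | None = field(default=None, repr=False)


def predictive_accuracy(spec: DecisionModelSpec, params: Mapping,
                        session: pd.DataFrame, epsilons: np.ndarray,
                        context: Mapping | None = None) -> float:
    """Fraction of trials on which the model's argmax choice (accept iff
    q >= 0.5) agrees with the observed choice."""
    v = trial_values(spec, session, epsilons,
                     {k: v for k, v in params.items() if k != "beta"}, context)
    predicted = (accept_probability(v, params["beta"]) >= 0.5).astype(int)
    return float(np.mean(predicted == session["choice"].to_numpy()))


def fit_model(spec: DecisionModelSpec, session: pd.DataFrame,
              epsilons: np.ndarray, context: Mapping | None = None,
              grid_points: int = DEFAULT_GRID_POINTS,
              store_posterior: bool = True) -> FitResult:
    """Fit one model by the full joint grid posterior.

    The posterior is exp(lnL) times the uniform grid prior, normalised;
    point estimates are posterior means; accuracy uses the deterministic
    q >= 0.5 rule at those estimates.
    """
    grid = build_grid(spec, grid_points)
    loglik, _ = grid_log_likelihood(spec, session, epsilons, grid, context)
    max_ll = float(loglik.max())
    post = np.exp(loglik - max_ll)
    post /= post.sum()

    estimates = {}
    for i, name in enumerate(grid.names):
        axes = tuple(j for j in range(post.ndim) if j != i)
        estimates[name] = float((post.sum(axis=axes) * grid.nodes[i]).sum())

    v = trial_values(spec, session, epsilons,
                     {k: val for k, val in estimates.items() if k != "beta"},
                     context)
    q = accept_probability(v, estimates["beta"])
    predicted = (q >= 0.5).astype(int)
    accuracy = float(np.mean(predicted == session["choice"].to_numpy()))
    n = len(session)
    return FitResult(
        model_id=spec.id,
        model_name=spec.name,
        params=estimates,
        max_loglik=max_ll,
        bic=bic(max_ll, spec.k, n),
        accuracy=accuracy,
        n_trials=n,
        q_accept=np.asarray(q, float),
        posterior=post if store_posterior else None,
        grid=grid if store_posterior else None,
    )


# --- model selection ------------------------------------------------------

def _dirichlet_bms(log_evidence: np.ndarray, n_samples: int = 100_000,
                   seed: int = 0, max_iter: int = 200, tol: float = 1e-8):
    """Random-effects model selection (variational Dirichlet scheme).

    ``log_evidence`` has shape (n_subjects, n_models).  Returns the
    Dirichlet parameters, expected model frequencies and exceedance
    probabilities (the latter by seeded Monte-Carlo over the fitted
    Dirichlet).
    """
    L = np.asarray(log_evidence, float)
    n_sub, n_mod = L.shape
    alpha0 = np.ones(n_mod)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        log_u = L + digamma(alpha) - digamma(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        g = np.exp(log_u)
        g /= g.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    freq = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=n_mod) / n_samples
    return alpha, freq, xp


def select_models(fits: Mapping[int, Sequence[FitResult]],
                  seed: int = 0) -> dict:
    """Compare models fit to every participant.

    ``fits`` maps model id -> one FitResult per participant (same
    participant order in every list).  Reports the group-summed BIC
    ranking and random-effects selection quantities with -BIC/2 as the
    per-participant log model evidence.
    """
    model_ids = sorted(fits)
    n_sub = {len(fits[m]) for m in model_ids}
    if len(n_sub) != 1:
        raise ValueError("all models must be fit to the same participants")
    bic_matrix = np.array([[f.bic for f in fits[m]] for m in model_ids]).T
    summed = bic_matrix.sum(axis=0)
    alpha, freq, xp = _dirichlet_bms(-bic_matrix / 2.0, seed=seed)
    order = np.argsort(summed)
    return {
        "model_ids": model_ids,
        "summed_bic": dict(zip(model_ids, summed.tolist())),
        "best_bic": model_ids[int(order[0])],
        "alpha": dict(zip(model_ids, alpha.tolist())),
        "expected_freq": dict(zip(model_ids, freq.tolist())),
        "exceedance": dict(zip(model_ids, xp.tolist())),
        "best_exceedance": model_ids[int(np.argmax(xp))],
    }


# --- generate-recover -----------------------------------------------------

def model_policy(spec: DecisionModelSpec, params: Mapping,
                 weighting=None, rng: np.random.Generator | int = 0,
                 context: Mapping | None = None,
                 stochastic: bool = True) -> Callable:
    """Responder policy drawing choices from a decision model.

    Perceived valence defaults to the displayed valence (identity
    weighting); pass a ``WeightingParams`` to perceive faces nonlinearly.
    With ``stochastic=False`` the policy applies the argmax rule instead of
    sampling Bernoulli(q).
    """
    from .perception import weighting_function

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    free = {k: v for k, v in params.items() if k != "beta"}
    beta = params["beta"]
    ctx = dict(context or {})

    def policy(phi, offer, history):
        eps = weighting_function(phi, weighting) if weighting is not None else phi
        R_S = offer / PENCE_PER_POUND
        R_O = (1000 - offer) / PENCE_PER_POUND
        v = float(spec.values(R_S, R_O, eps, free, ctx))
        q = accept_probability(v, beta)
        if stochastic:
            return int(rng.random() < q)
        return int(q >= 0.5)

    return policy


def default_truth_sampler(rng: np.random.Generator) -> dict:
    """Plausible, identifiable regime for the parabolic inequality model
    (pound scale): kappa ~ U[0.5, 2], omega ~ U[-4, -1], beta = 2 +/- 20%."""
    return {
        "kappa": float(rng.uniform(0.5, 2.0)),
        "omega": float(rng.uniform(-4.0, -1.0)),
        "beta": float(2.0 * rng.uniform(0.8, 1.2)),
    }


def generate_recover(spec: DecisionModelSpec | int = 10,
                     n_iterations: int = 50,
                     truth_sampler: Callable | None = None,
                     seed: int = 0,
                     grid_points: int = DEFAULT_GRID_POINTS,
                     n_blocks: int = 6,
                     trials_per_block: int = 40) -> dict:
    """Generate-recover stability analysis of one model's estimator.

    Each iteration samples true parameters, simulates a closed-loop session
    with the model as the (stochastic) responder, refits the model on the
    simulated choices, and records the posterior-mean estimates.  Reports
    per-parameter Pearson correlation and mean bias between truth and
    recovery across iterations.
    """
    if isinstance(spec, int):
        spec = get_model(spec)
    sampler = truth_sampler or default_truth_sampler
    master = np.random.default_rng(seed)
    truths, recovered = [], []
    for _ in range(n_iterations):
        truth = sampler(master)
        sess_rng = np.random.default_rng(master.integers(2**31))
        policy = model_policy(spec, truth, rng=sess_rng)
        session = task_engine.run_session(
            policy, n_blocks=n_blocks, trials_per_block=trials_per_block,
            seed=np.random.default_rng(master.integers(2**31)))
        eps = session["phi"].to_numpy(float)  # identity perception
        fit = fit_model(spec, session, eps, grid_points=grid_points,
                        store_posterior=False)
        truths.append(truth)
        recovered.append(fit.params)
    names = list(truths[0])
    report = {"n_iterations": n_iterations, "params": {}}
    for name in names:
        t = np.array([tr[name] for tr in truths])
        r = np.array([rc[name] for rc in recovered])
        corr = float(pearsonr(t, r)[0]) if np.std(t) > 0 else np.nan
        report["params"][name] = {
            "true": t, "recovered": r,
            "pearson_r": corr,
            "bias": float(np.mean(r - t)),
        }
    return report
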