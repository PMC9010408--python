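"""Models of how raters perceive facial affect and Ultimatum offers.

Faces: Likert ratings (1..9, divided by 10 onto the unit interval) of faces
with true valence ``phi`` are fit with the two-parameter Prelec probability
weighting function

    epsilon = exp(-delta * (-ln(phi)) ** gamma)

whose curvature (gamma) and elevation (delta) capture the nonlinearity of
facial-emotion recognition; delta = gamma = 1 is the identity.

Offers: liking ratings chi of a split (R_S to the rater, R_O to the
proposer) follow a linear model chi = phi0 + phi1*R_S + phi2*|R_S - R_O|,
where a negative phi2 expresses aversion to inequality.  R_O never enters
separately because the pot is fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "MU_CROSSOVER",
    "WeightingParams",
    "LikingParams",
    "weighting_function",
    "fit_weighting",
    "fit_liking",
]

#: group-level crossover of the weighting function with the diagonal;
#: enters the emotion-modulated decision models as (epsilon - mu).
MU_CROSSOVER = 0.4


@dataclass(frozen=True)
class WeightingParams:
    """Prelec weighting parameters; both must be finite and positive."""

    delta: float
    gamma: float

    def __post_init__(self):
        if not (np.isfinite(self.delta) and self.delta > 0):
            raise ValueError("delta must be finite and positive")
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError("gamma must be finite and positive")


@dataclass(frozen=True)
class LikingParams:
    """Offer-liking regression coefficients (Likert units)."""

    phi0: float
    phi1: float
    phi2: float


def weighting_function(phi, params: WeightingParams | None = None, *,
                       delta: float | None = None, gamma: float | None = None):
    """Perceived valence of a face with true valence ``phi`` in (0, 1).

    Strictly increasing in phi for positive parameters and maps (0,1) into
    (0,1); the identity when delta = gamma = 1.
    """
    if params is not None:
        delta, gamma = params.delta, params.gamma
    if delta is None or gamma is None:
        raise TypeError("provide WeightingParams or delta and gamma")
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr <= 0) or np.any(phi_arr >= 1):
        raise ValueError("phi must lie strictly inside (0, 1)")
    out = np.exp(-delta * (-np.log(phi_arr)) ** gamma)
    return float(out) if np.isscalar(phi) else out


def _weighting_residuals(theta, phi, target):
    delta, gamma = np.exp(theta)  # optimise on the log scale, keeps positivity
    return np.exp(-delta * (-np.log(phi)) ** gamma) - target


def fit_weighting(
    ratings: pd.DataFrame,
    bounds: tuple[float, float] = (0.01, 5.0),
    n_starts: int = 5,
    tol: float = 1e-9,
) -> dict:
    """Least-squares fit of the weighting function to face ratings.

    ``ratings`` needs columns ``phi`` (true valence) and ``likert`` (1..9);
    ratings are divided by 10 so that data and model share the unit scale.
    A 5x5 log-spaced multi-start lattice over (delta, gamma) guards against
    local minima; the best-of-starts solution is returned.
    """
    phi = ratings["phi"].to_numpy(dtype=float)
    target = ratings["likert"].to_numpy(dtype=float) / 10.0
    if len(np.unique(phi)) < 2:
        raise ValueError("need ratings at two or more distinct phi values")

    degenerate = np.allclose(target, target[0])
    if degenerate:
        warnings.warn("all face ratings identical; weighting fit is degenerate")

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    starts = np.linspace(lo, hi, n_starts)
    best = None
    for d0 in starts:
        for g0 in starts:
            res = least_squares(
                _weighting_residuals,
                x0=[d0, g0],
                args=(phi, target),
                bounds=([lo, lo], [hi, hi]),
                ftol=tol, xtol=tol, gtol=tol,
            )
            if best is None or res.cost < best.cost - 0.0:
                best = res
    delta, gamma = np.exp(best.x)
    sse = 2.0 * best.cost
    return {
        "params": WeightingParams(delta=float(delta), gamma=float(gamma)),
        "sse": float(sse),
        "n": len(phi),
        "degenerate": bool(degenerate),
    }


def fit_liking(ratings: pd.DataFrame) -> LikingParams:
    """OLS fit of the liking model to offer ratings.

    ``ratings`` needs columns ``R_S``, ``R_O`` (pence) and ``likert``
    (1..9; fit on the raw Likert scale — only face ratings are mapped to
    the unit interval, because only they must match the weighting
    function's range).  Raises on a rank-deficient design.
    """
    rs = ratings["R_S"].to_numpy(dtype=float)
    ro = ratings["R_O"].to_numpy(dtype=float)
    y = ratings["likert"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(rs), rs, np.abs(rs - ro)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient liking design: need >=3 independent "
                         "(R_S, |R_S-R_O|) combinations")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return LikingParams(phi0=float(coef[0]), phi1=float(coef[1]), phi2=float(coef[2]))
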