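"""Model-free behavioural analyses of UG sessions.

Per-participant summaries (acceptance heat map over the face x offer grid,
OLS main effects, lagged history logistic regression, misprediction
regression) feed group-level one-sample t-tests on the per-participant
coefficients — the standard two-stage summary-statistics approach, no
hierarchical model.  Face regressors use the true displayed valence, not
the fitted perception, because these analyses are model-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .task_engine import StateSpace, make_state_space

__all__ = [
    "AcceptanceGrid",
    "acceptance_grid",
    "main_effects_ols",
    "history_design",
    "history_logistic",
    "history_logistic_cohort",
    "vif",
    "misprediction_analysis",
    "misprediction_cohort",
    "parameter_covariates_ols",
    "expected_outcome",
    "group_ttests",
]

VIF_CAP = 1e6


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - np.mean(x)) / sd


def group_ttests(coef_matrix: np.ndarray, names: list[str]) -> pd.DataFrame:
    """One-sample t-tests against 0 on per-participant coefficients.

    ``coef_matrix`` is (n_participants, n_regressors); Cohen's d is the
    coefficient mean over its SD.
    """
    coef_matrix = np.asarray(coef_matrix, float)
    n = coef_matrix.shape[0]
    mean = coef_matrix.mean(axis=0)
    sd = coef_matrix.std(axis=0, ddof=1) if n > 1 else np.full(coef_matrix.shape[1], np.nan)
    t, p = (stats.ttest_1samp(coef_matrix, 0.0, axis=0) if n > 1
            else (np.full(coef_matrix.shape[1], np.nan),) * 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = mean / sd
    return pd.DataFrame({"regressor": names, "mean": mean, "sd": sd,
                         "t": np.asarray(t, float), "p": np.asarray(p, float),
                         "cohens_d": d, "df": n - 1})


@dataclass
class AcceptanceGrid:
    """Binned acceptance probabilities on the face x offer grid."""

    space: StateSpace
    prob: np.ndarray     # (n_faces, n_offers); NaN where unvisited
    counts: np.ndarray   # trials per cell

    def cells(self) -> pd.DataFrame:
        """Visited cells as long-format rows (phi, offer_pence, prob, count)."""
        fi, oi = np.nonzero(self.counts)
        return pd.DataFrame({
            "phi": self.space.phi[fi],
            "offer_pence": self.space.offers[oi],
            "prob": self.prob[fi, oi],
            "count": self.counts[fi, oi],
        })


def acceptance_grid(sessions: pd.DataFrame | list[pd.DataFrame],
                    space: StateSpace | None = None) -> AcceptanceGrid:
    """Average acceptance probability per (face, offer) cell.

    Accepts one session table or a list (concatenated).  Unvisited cells
    are NaN, not zero.
    """
    sp = space if space is not None else make_state_space()
    if isinstance(sessions, list):
        sessions = pd.concat(sessions, ignore_index=True)
    counts = np.zeros((sp.n_faces, sp.n_offers), dtype=int)
    accepts = np.zeros_like(counts)
    fi = sessions["face_index"].to_numpy(int) - 1
    oi = np.searchsorted(sp.offers, sessions["offer_pence"].to_numpy(int))
    np.add.at(counts, (fi, oi), 1)
    np.add.at(accepts, (fi, oi), sessions["choice"].to_numpy(int))
    with np.errstate(invalid="ignore"):
        prob = np.where(counts > 0, accepts / np.maximum(counts, 1), np.nan)
    return AcceptanceGrid(space=sp, prob=prob, counts=counts)


def _main_effect_coefs(grid: AcceptanceGrid) -> np.ndarray:
    cells = grid.cells()
    face = _zscore(cells["phi"].to_numpy(float))
    offer = _zscore(cells["offer_pence"].to_numpy(float))
    inter = _zscore(cells["phi"].to_numpy(float) * cells["offer_pence"].to_numpy(float))
    X = np.column_stack([np.ones(len(cells)), face, offer, inter])
    coef, *_ = np.linalg.lstsq(X, cells["prob"].to_numpy(float), rcond=None)
    return coef


MAIN_EFFECT_NAMES = ["intercept", "face", "offer", "face_x_offer"]


def main_effects_ols(grids: list[AcceptanceGrid]) -> dict:
    """Per-participant OLS on binned acceptance, then group t-tests.

    Regressors (z-scored within participant): face valence, offer amount
    and their interaction; unvisited cells are excluded.
    """
    coefs = np.array([_main_effect_coefs(g) for g in grids])
    return {"coefficients": coefs,
            "names": MAIN_EFFECT_NAMES,
            "group": group_ttests(coefs, MAIN_EFFECT_NAMES)}


# --- lagged history logistic regression -----------------------------------

def history_design(session: pd.DataFrame, lags: int = 3) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Lagged design for the history regression.

    For every trial with ``lags`` predecessors *within the same block*,
    regressors from trials t-1 .. t-lags: face valence, offer, face x offer
    and the previous choice (4 per lag), z-scored across rows.  Returns
    (X without intercept, y, names).
    """
    rows, ys = [], []
    names = [f"{base}_lag{k}" for k in range(1, lags + 1)
             for base in ("face", "offer", "face_x_offer", "choice")]
    for _, block in session.groupby("block"):
        phi = block["phi"].to_numpy(float)
        offer = block["offer_pence"].to_numpy(float)
        choice = block["choice"].to_numpy(float)
        for t in range(lags, len(block)):
            feats = []
            for k in range(1, lags + 1):
                feats.extend([phi[t - k], offer[t - k],
                              phi[t - k] * offer[t - k], choice[t - k]])
            rows.append(feats)
            ys.append(choice[t])
    X = np.asarray(rows, float)
    X = np.apply_along_axis(_zscore, 0, X)
    return X, np.asarray(ys, float), names


def history_logistic(session: pd.DataFrame, lags: int = 3,
                     ridge: float = 1e-4) -> dict:
    """Logistic regression of the current choice on the lagged history.

    Falls back to a small ridge penalty (with a warning) when the maximum
    likelihood fit fails through separation — deterministic policies
    otherwise break the fit.
    """
    X, y, names = history_design(session, lags)
    Xc = sm.add_constant(X, has_constant="add")
    coef = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 50:
                coef = np.asarray(res.params)
        except Exception:
            coef = None
    if coef is None:
        warnings.warn("logistic fit unstable (separation?); using ridge fallback")
        res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit_regularized(
            alpha=ridge, L1_wt=0.0)
        coef = np.asarray(res.params)
    return {"coefficients": coef[1:], "intercept": coef[0],
            "names": names, "n": len(y)}


def history_logistic_cohort(sessions: list[pd.DataFrame], lags: int = 3) -> dict:
    """Per-participant history logistic fits plus group t-tests."""
    fits = [history_logistic(s, lags) for s in sessions]
    coefs = np.array([f["coefficients"] for f in fits])
    names = fits[0]["names"]
    return {"coefficients": coefs, "names": names,
            "group": group_ttests(coefs, names)}


def vif(X: np.ndarray, names: list[str] | None = None) -> pd.DataFrame:
    """Variance inflation factor 1/(1 - R^2) per regressor.

    Each column is regressed on the remaining columns (plus an intercept).
    Perfectly collinear columns are reported capped at 1e6 and flagged.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    out = []
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        tss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
        if 1.0 - r2 < 1.0 / VIF_CAP:
            out.append((VIF_CAP, True))
        else:
            out.append((1.0 / (1.0 - r2), False))
    return pd.DataFrame({
        "regressor": names if names is not None else [f"x{j}" for j in range(p)],
        "vif": [v for v, _ in out],
        "collinear": [c for _, c in out],
    })


# --- misprediction analysis ----------------------------------------------

def misprediction_analysis(predicted: np.ndarray, session: pd.DataFrame) -> dict:
    """OLS of the misprediction indicator on face, offer and interaction.

    ``predicted`` holds the model's argmax choices per trial.  With no
    mispredicted trial, the indicator is constant and coefficients are 0.
    """
    mis = (np.asarray(predicted, int) != session["choice"].to_numpy(int)).astype(float)
    face = _zscore(session["phi"].to_numpy(float))
    offer = _zscore(session["offer_pence"].to_numpy(float))
    inter = _zscore(session["phi"].to_numpy(float) * session["offer_pence"].to_numpy(float))
    X = np.column_stack([np.ones(len(session)), face, offer, inter])
    coef, *_ = np.linalg.lstsq(X, mis, rcond=None)
    return {"coefficients": coef, "names": MAIN_EFFECT_NAMES,
            "n_mispredicted": int(mis.sum()), "rate": float(mis.mean())}


def misprediction_cohort(predictions: list[np.ndarray],
                         sessions: list[pd.DataFrame]) -> dict:
    """Group t-tests on per-participant misprediction regressions."""
    reports = [misprediction_analysis(p, s) for p, s in zip(predictions, sessions)]
    coefs = np.array([r["coefficients"] for r in reports])
    return {"coefficients": coefs, "names": MAIN_EFFECT_NAMES,
            "group": group_ttests(coefs, MAIN_EFFECT_NAMES),
            "rates": [r["rate"] for r in reports]}


def parameter_covariates_ols(estimates: np.ndarray,
                             covariates: pd.DataFrame) -> dict:
    """OLS of a fitted parameter on normalised participant covariates.

    Covariates are z-scored, so the intercept equals the mean parameter
    value.  Returns coefficient estimates with t and p values.
    """
    y = np.asarray(estimates, float)
    names = list(covariates.columns)
    Z = np.column_stack([_zscore(covariates[c].to_numpy(float)) for c in names])
    X = sm.add_constant(Z, has_constant="add")
    res = sm.OLS(y, X).fit()
    return {
        "names": ["intercept"] + names,
        "coefficients": np.asarray(res.params),
        "t": np.asarray(res.tvalues),
        "p": np.asarray(res.pvalues),
        "df": int(res.df_resid),
    }


def expected_outcome(session: pd.DataFrame) -> float:
    """Expected per-trial payment: mean acceptance rate times mean offer."""
    return float(session["choice"].mean() * session["offer_pence"].mean())
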