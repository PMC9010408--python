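"""Recursive Bayesian filtering of the stimulus streams.

An ideal observer tracks the generative statistics of a scalar stream (the
offers, or the face valences) under a simple hierarchical model: a latent
mean performs a Gaussian random walk whose step SD is the environmental
*volatility*; observations are the latent mean plus Gaussian *noise*.  The
filter maintains the full joint posterior over (latent mean, volatility,
noise SD) on a fixed 3-D grid and, for every observation, emits

* the posterior mean volatility and noise (how changeable and how noisy
  the environment currently appears), and
* *surprise*, the negative log of the grid-marginal predictive density of
  the observation — large when a stimulus violates expectations.

Run separately on the offer and face streams this yields the six nuisance
regressors of the pupillary regression.  The internal model is a
documented reconstruction (the published filter's exact state space is not
reproduced here); its outputs are used only as trial-wise regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "FilterConfig",
    "FilterTrajectory",
    "default_config",
    "filter_stream",
    "surprise",
    "session_filter_regressors",
    "FILTER_REGRESSOR_COLUMNS",
]

FILTER_REGRESSOR_COLUMNS = [
    "surprise_offer", "surprise_face",
    "vol_offer", "vol_face",
    "noise_offer", "noise_face",
]


@dataclass(frozen=True)
class FilterConfig:
    """Grid nodes of the filter's joint state space."""

    mean_nodes: np.ndarray
    vol_nodes: np.ndarray     # random-walk step SD, > 0
    noise_nodes: np.ndarray   # observation SD, > 0

    def __post_init__(self):
        if np.any(np.asarray(self.vol_nodes) <= 0) or np.any(np.asarray(self.noise_nodes) <= 0):
            raise ValueError("volatility and noise nodes must be positive")


def default_config(observations: np.ndarray,
                   n_mean: int = 61, n_vol: int = 21, n_noise: int = 21) -> FilterConfig:
    """Grid spanning the observation range +/- 20%, log-spaced vol/noise."""
    obs = np.asarray(observations, float)
    lo, hi = obs.min(), obs.max()
    span = hi - lo
    if span == 0:
        span = max(abs(hi), 1.0)
        lo, hi = lo - span / 2, hi + span / 2
    pad = 0.2 * span
    return FilterConfig(
        mean_nodes=np.linspace(lo - pad, hi + pad, n_mean),
        vol_nodes=np.geomspace(0.005 * span, 0.5 * span, n_vol),
        noise_nodes=np.geomspace(0.01 * span, 1.0 * span, n_noise),
    )


@dataclass
class FilterTrajectory:
    """Per-observation filter outputs and the final joint posterior."""

    vol: np.ndarray
    noise: np.ndarray
    surprise: np.ndarray
    pred_mean: np.ndarray      # predictive mean of each observation
    pred_sd: np.ndarray        # predictive SD of each observation
    posterior: np.ndarray = field(repr=False)   # (n_mean, n_vol, n_noise)
    config: FilterConfig = field(repr=False, default=None)


def surprise(observation: float, mean, sd) -> float:
    """Negative log Gaussian density of an observation: -ln N(obs; mean, sd)."""
    return float(-norm.logpdf(observation, loc=mean, scale=sd))


def filter_stream(observations, config: FilterConfig | None = None) -> FilterTrajectory:
    """Run the predict-update cycle over a scalar stream.

    The prior over the joint grid is uniform.  Each step first diffuses the
    latent-mean marginal by the volatility of its slice (predict), then
    scores the observation under the grid-marginal predictive density
    (surprise), then multiplies in the Gaussian likelihood (update).
    """
    obs = np.asarray(observations, float)
    if obs.ndim != 1 or len(obs) == 0:
        raise ValueError("observations must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(obs)):
        raise ValueError("non-finite observations rejected")
    cfg = config if config is not None else default_config(obs)
    m = np.asarray(cfg.mean_nodes, float)
    v = np.asarray(cfg.vol_nodes, float)
    s = np.asarray(cfg.noise_nodes, float)
    nm, nv, ns = len(m), len(v), len(s)

    # random-walk transition kernel per volatility node, columns normalised
    diff = m[:, None] - m[None, :]                       # (m', m)
    T = norm.pdf(diff[None, :, :], scale=v[:, None, None])  # (v, m', m)
    T /= T.sum(axis=1, keepdims=True)

    # Gaussian likelihood of each possible observation node pair is built
    # per observation; posterior axes are (mean, vol, noise)
    post = np.full((nm, nv, ns), 1.0 / (nm * nv * ns))

    out_vol = np.empty(len(obs))
    out_noise = np.empty(len(obs))
    out_surprise = np.empty(len(obs))
    out_pm = np.empty(len(obs))
    out_ps = np.empty(len(obs))

    for t, y in enumerate(obs):
        # predict: diffuse the mean within each (vol, noise) slice
        p = np.einsum("vij,jvs->ivs", T, post)
        # predictive density of y: mixture of N(y; m, s) over the grid
        like = norm.pdf(y, loc=m[:, None], scale=s[None, :])   # (m, s)
        pred = float(np.einsum("ivs,is->", p, like))
        out_surprise[t] = -np.log(max(pred, 1e-300))
        # predictive moments of the mixture
        w = p.sum(axis=1)                                      # (m, s)
        mu = float(np.einsum("is,i->", w, m))
        var = float(np.einsum("is,i->", w, m ** 2)) - mu ** 2 \
            + float(np.einsum("is,s->", w, s ** 2))
        out_pm[t] = mu
        out_ps[t] = np.sqrt(max(var, 0.0))
        # update
        post = p * like[:, None, :]
        post /= post.sum()
        out_vol[t] = float(post.sum(axis=(0, 2)) @ v)
        out_noise[t] = float(post.sum(axis=(0, 1)) @ s)

    return FilterTrajectory(vol=out_vol, noise=out_noise, surprise=out_surprise,
                            pred_mean=out_pm, pred_sd=out_ps,
                            posterior=post, config=cfg)


def session_filter_regressors(session: pd.DataFrame,
                              offer_config: FilterConfig | None = None,
                              face_config: FilterConfig | None = None) -> pd.DataFrame:
    """Six per-trial nuisance regressors from the two stimulus streams.

    Offers are standardised to pounds and faces filtered on the (0, 1)
    valence scale, so one default grid construction serves both streams.
    """
    offers = session["offer_pence"].to_numpy(float) / 100.0
    faces = session["phi"].to_numpy(float)
    fo = filter_stream(offers, offer_config)
    ff = filter_stream(faces, face_config)
    return pd.DataFrame({
        "surprise_offer": fo.surprise,
        "surprise_face": ff.surprise,
        "vol_offer": fo.vol,
        "vol_face": ff.vol,
        "noise_offer": fo.noise,
        "noise_face": ff.noise,
    })
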