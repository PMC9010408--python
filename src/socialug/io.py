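"""Readers and writers for the package's text formats.

All artefacts are plain text: session logs and rating tables as CSV, pupil
sample streams as TSV, fit results as JSON.  Readers validate schemas on
load and name the offending row in error messages.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import FitResult
from .task_engine import SESSION_COLUMNS

__all__ = [
    "read_session", "write_session",
    "read_ratings", "write_ratings",
    "read_pupil_samples", "write_pupil_samples",
    "read_events", "write_events",
    "fit_to_json", "fit_from_json",
]

RATING_COLUMNS = ["stimulus_type", "phi", "R_S", "R_O", "repetition", "likert"]
SAMPLE_COLUMNS = ["time_ms", "pupil", "valid"]
EVENT_COLUMNS = ["trial", "event_name", "time_ms"]


def _check_header(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def write_session(session: pd.DataFrame, path) -> None:
    session.to_csv(path, index=False, columns=SESSION_COLUMNS)


def read_session(path, pot: int = 1000) -> pd.DataFrame:
    """Load and validate a session CSV (one row per trial)."""
    df = pd.read_csv(path)
    _check_header(df, SESSION_COLUMNS, path)
    bad = df.index[~df["choice"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"{path}: row {bad[0] + 2} has choice = "
                         f"{df.loc[bad[0], 'choice']!r}, expected 0 or 1")
    bad = df.index[df["offer_pence"] + df["other_pence"] != pot]
    if len(bad):
        raise ValueError(f"{path}: row {bad[0] + 2} splits do not sum to the pot")
    bad = df.index[df["outcome_self"] != df["offer_pence"] * df["choice"]]
    if len(bad):
        raise ValueError(f"{path}: row {bad[0] + 2} has inconsistent outcome_self")
    return df[SESSION_COLUMNS]


def write_ratings(ratings: pd.DataFrame, path) -> None:
    ratings.to_csv(path, index=False, columns=RATING_COLUMNS)


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, RATING_COLUMNS, path)
    bad = df.index[~df["likert"].isin(range(1, 10))]
    if len(bad):
        raise ValueError(f"{path}: row {bad[0] + 2} has likert outside 1..9")
    if not df["stimulus_type"].isin(["face", "offer"]).all():
        raise ValueError(f"{path}: stimulus_type must be 'face' or 'offer'")
    return df


def write_pupil_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False, columns=SAMPLE_COLUMNS)


def read_pupil_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_header(df, SAMPLE_COLUMNS, path)
    return df


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False, columns=EVENT_COLUMNS)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, EVENT_COLUMNS, path)
    return df


def fit_to_json(fit: FitResult, path=None) -> str:
    """Serialise a fit (without the grid posterior) to JSON text."""
    payload = {
        "model_id": fit.model_id,
        "model_name": fit.model_name,
        "params": fit.params,
        "max_loglik": fit.max_loglik,
        "bic": fit.bic,
        "accuracy": fit.accuracy,
        "n_trials": fit.n_trials,
        "q_accept": np.asarray(fit.q_accept).tolist(),
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def fit_from_json(source) -> FitResult:
    """Load a fit written by :func:`fit_to_json` (path or JSON text)."""
    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    d = json.loads(text)
    return FitResult(
        model_id=d["model_id"], model_name=d["model_name"],
        params=d["params"], max_loglik=d["max_loglik"], bic=d["bic"],
        accuracy=d["accuracy"], n_trials=d["n_trials"],
        q_accept=np.asarray(d["q_accept"], float),
    )
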