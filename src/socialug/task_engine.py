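"""Closed-loop iterative Ultimatum Game engine.

The proposer is a computerised strategy that samples its next facial emotion
and next offer from two independent sliding windows: on every trial the face
and the offer may each stay put or step to a neighbouring level, with
response-conditioned transition probabilities (after an accept the face is
more likely to step towards positive affect and the offer to drift down;
after a reject the reverse).  Each block restarts from a neutral face and a
fair 50/50 split, so the responder experiences a gradually evolving
negotiation whose stimulus stream depends on their own choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "StateSpace",
    "TransitionTable",
    "DEFAULT_FACE_TABLE",
    "DEFAULT_OFFER_TABLE",
    "SESSION_COLUMNS",
    "make_state_space",
    "sample_next_level",
    "sample_next_face",
    "sample_next_offer",
    "run_session",
    "select_payout_trials",
    "accept_all_policy",
    "reject_all_policy",
    "offer_threshold_policy",
]

#: canonical column order of a session table (one row per trial)
SESSION_COLUMNS = [
    "trial",
    "block",
    "face_index",
    "phi",
    "offer_pence",
    "other_pence",
    "choice",
    "outcome_self",
    "outcome_other",
    "reaction_face_index",
    "rt_ms",
]


@dataclass(frozen=True)
class StateSpace:
    """The joint stimulus space of the task.

    Faces are indexed 1..n_faces from most negative to most positive; each
    carries a true valence ``phi`` on the open unit interval.  Offers are the
    responder's share in pence on a regular grid; the proposer keeps
    ``pot - offer``.
    """

    phi: np.ndarray          # true valence per face level, increasing
    offers: np.ndarray       # offer levels in pence, increasing
    pot: int = 1000

    @property
    def n_faces(self) -> int:
        return len(self.phi)

    @property
    def n_offers(self) -> int:
        return len(self.offers)

    @property
    def n_states(self) -> int:
        """Size of the joint face x offer space."""
        return self.n_faces * self.n_offers

    @property
    def neutral_face(self) -> int:
        """1-based index of the middle (neutral) face."""
        return (self.n_faces + 1) // 2

    @property
    def fair_offer(self) -> int:
        """The 50/50 split in pence."""
        return self.pot // 2

    def face_phi(self, index: int) -> float:
        """Valence of the 1-based face ``index``."""
        if not 1 <= index <= self.n_faces:
            raise ValueError(f"face index {index} outside 1..{self.n_faces}")
        return float(self.phi[index - 1])

    def offer_index(self, offer: int) -> int:
        """1-based grid position of an offer in pence."""
        pos = np.searchsorted(self.offers, offer)
        if pos >= self.n_offers or self.offers[pos] != offer:
            raise ValueError(f"offer {offer} not on the grid")
        return int(pos) + 1


def make_state_space(
    n_faces: int = 9,
    offer_min: int = 50,
    offer_max: int = 950,
    offer_step: int = 50,
    pot: int = 1000,
) -> StateSpace:
    """Build the task's stimulus space (default: 9 faces x 19 offers = 171).

    Face valences are evenly spaced on (0, 1): with 9 faces they run 0.1,
    0.2, ..., 0.9.  Enumeration of the joint space is face-major (all offers
    for face 1, then face 2, ...).
    """
    if n_faces < 1:
        raise ValueError("need at least one face level")
    if offer_max > pot:
        raise ValueError("offers cannot exceed the pot")
    if offer_min < 0 or offer_min > offer_max:
        raise ValueError("invalid offer range")
    if offer_max > offer_min and (offer_max - offer_min) % offer_step != 0:
        raise ValueError("offer step does not divide the offer range")
    phi = (np.arange(1, n_faces + 1)) / (n_faces + 1)
    offers = np.arange(offer_min, offer_max + 1, offer_step, dtype=int)
    return StateSpace(phi=phi, offers=offers, pot=pot)


@dataclass(frozen=True)
class TransitionTable:
    """Response-conditioned sliding-window move probabilities.

    Each row is (P(step -1), P(stay), P(step +1)) and applies uniformly to
    every level of the stream; at the grid boundary the out-of-range mass is
    dropped and the row renormalised (clamp-and-renormalise), which preserves
    the relative stay/step odds.
    """

    accept: tuple[float, float, float]
    reject: tuple[float, float, float]

    def __post_init__(self):
        for name, row in (("accept", self.accept), ("reject", self.reject)):
            row = np.asarray(row, dtype=float)
            if row.shape != (3,):
                raise ValueError(f"{name} row must have 3 entries")
            if np.any(row < 0):
                raise ValueError(f"{name} row has negative mass")
            if abs(row.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} row sums to {row.sum()}, not 1")

    def row(self, choice: int) -> np.ndarray:
        return np.asarray(self.accept if choice else self.reject, dtype=float)


# Default tables matching the qualitative proposer strategy: happier faces
# after accepts, angrier after rejects; offers probe around the acceptance
# threshold (drift down after accepts, up after rejects).
DEFAULT_FACE_TABLE = TransitionTable(accept=(0.1, 0.3, 0.6), reject=(0.6, 0.3, 0.1))
DEFAULT_OFFER_TABLE = TransitionTable(accept=(0.5, 0.35, 0.15), reject=(0.15, 0.35, 0.5))


def sample_next_level(
    current: int,
    choice: int,
    table: TransitionTable,
    rng: np.random.Generator,
    n_levels: int,
) -> int:
    """Draw the next level (1-based) of one stream given the last response.

    Moves are restricted to {-1, 0, +1}; at the boundary the out-of-range
    move gets zero mass and the row is renormalised.
    """
    if not 1 <= current <= n_levels:
        raise ValueError(f"level {current} outside 1..{n_levels}")
    probs = table.row(choice).copy()
    if current == 1:
        probs[0] = 0.0
    if current == n_levels:
        probs[2] = 0.0
    total = probs.sum()
    if total <= 0:
        raise ValueError("all transition mass out of range")
    move = rng.choice([-1, 0, 1], p=probs / total)
    return current + int(move)


def sample_next_face(
    current: int,
    choice: int,
    table: TransitionTable,
    rng: np.random.Generator,
    space: StateSpace | None = None,
) -> int:
    """Next face index after a choice (1 = most negative)."""
    n = space.n_faces if space is not None else 9
    return sample_next_level(current, choice, table, rng, n)


def sample_next_offer(
    current: int,
    choice: int,
    table: TransitionTable,
    rng: np.random.Generator,
    space: StateSpace | None = None,
) -> int:
    """Next offer in pence after a choice (moves along the offer grid)."""
    sp = space if space is not None else make_state_space()
    idx = sp.offer_index(current)
    nxt = sample_next_level(idx, choice, table, rng, sp.n_offers)
    return int(sp.offers[nxt - 1])


# --- simple reference policies -------------------------------------------

def accept_all_policy(phi, offer, history) -> int:
    return 1


def reject_all_policy(phi, offer, history) -> int:
    return 0


def offer_threshold_policy(threshold: int) -> Callable:
    """Accept iff the offer is at least ``threshold`` pence."""

    def policy(phi, offer, history):
        return int(offer >= threshold)

    return policy


def run_session(
    policy: Callable,
    face_table: TransitionTable = DEFAULT_FACE_TABLE,
    offer_table: TransitionTable = DEFAULT_OFFER_TABLE,
    space: StateSpace | None = None,
    n_blocks: int = 6,
    trials_per_block: int = 40,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one closed-loop session; returns a session table.

    ``policy(phi, offer_pence, history) -> {0, 1}`` is the responder;
    ``history`` is the list of prior trial records (dicts) in order.
    Every block restarts at (neutral face, fair offer).  After each decision
    the proposer's reaction face is drawn from the face table and carries
    over as the next trial's pre-offer face; the next offer is drawn from
    the offer table.  Deterministic for a fixed integer seed.
    """
    sp = space if space is not None else make_state_space()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows: list[dict] = []
    trial = 0
    for block in range(1, n_blocks + 1):
        face = sp.neutral_face
        offer = sp.fair_offer
        for t in range(trials_per_block):
            trial += 1
            phi = sp.face_phi(face)
            other = sp.pot - offer
            choice = policy(phi, offer, rows)
            if choice not in (0, 1):
                raise ValueError(f"policy returned non-binary choice {choice!r}")
            choice = int(choice)
            reaction = sample_next_face(face, choice, face_table, rng, sp)
            rows.append(
                {
                    "trial": trial,
                    "block": block,
                    "face_index": face,
                    "phi": phi,
                    "offer_pence": offer,
                    "other_pence": other,
                    "choice": choice,
                    "outcome_self": offer * choice,
                    "outcome_other": other * choice,
                    "reaction_face_index": reaction,
                    "rt_ms": np.nan,
                }
            )
            face = reaction
            offer = sample_next_offer(offer, choice, offer_table, rng, sp)
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def select_payout_trials(
    session: pd.DataFrame,
    rng: np.random.Generator | int = 0,
    n_payout: int = 20,
) -> dict:
    """Randomly select payout trials irrespective of the choices made.

    Returns the selected trial indices (distinct, uniform without
    replacement) and the summed self-outcome over them in pence.
    """
    if len(session) < n_payout:
        raise ValueError(f"session has {len(session)} < {n_payout} trials")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    chosen = np.sort(rng.choice(session["trial"].to_numpy(), size=n_payout, replace=False))
    mask = session["trial"].isin(chosen)
    payout = int(session.loc[mask, "outcome_self"].sum())
    return {"trials": chosen.tolist(), "payout_pence": payout}
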