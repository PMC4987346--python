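"""Prediction engines: general simulation and one-step-ahead replay.

Both engines emit a *prediction matrix*: an (n_trials, 4) array whose row t
is the model's pre-choice probability of selecting each deck on trial t
(deck order A-D). Expectancies start at zero, so row 1 is always the
four-deck chance level (0.25 each).

* **General simulation** — the model plays the task itself: the first trial
  is drawn at chance, each outcome is dealt from the deck's own card stack
  (a deck's position advances only when that deck is picked), scored with
  prospect utility, and learned with the chosen rule. Stochastic but fully
  reproducible from a seed.
* **One-step-ahead** — the model replays a subject's observed choices and
  outcomes, and for every trial reports the probabilities it would have
  assigned *before* seeing that trial. Deterministic given data and
  parameters.

The internal path runner is vectorized across independent trajectories
(and, via broadcasting, across parameter sets), which is what makes the
exhaustive grid search in :mod:`igtpu.fitting` affordable.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .model import ParameterSet, choice_probabilities, pu_utility
from .task import DECKS, PayoffSchedule, deck_index

__all__ = ["simulate_game", "one_step_ahead", "average_simulations"]


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def rep_uniforms(seed, n_reps: int, n_trials: int) -> np.ndarray:
    """Pre-drawn choice uniforms, one row per repetition.

    One root seed; repetition r uses the r-th spawned child seed, so any
    single repetition can be reproduced in isolation by
    ``simulate_game(..., seed=child_r)``.
    """
    children = _seed_sequence(seed).spawn(n_reps)
    return np.stack([np.random.default_rng(c).random(n_trials) for c in children])


def _run_paths(
    alpha,
    lam,
    A,
    rule: str,
    theta: float,
    schedule: PayoffSchedule,
    U: np.ndarray,
    visit: Callable[[int, np.ndarray, np.ndarray, np.ndarray, np.ndarray], None],
) -> None:
    """Advance R independent game trajectories through T trials.

    ``U`` is an (R, T) array of pre-drawn uniforms (one per choice);
    ``alpha``/``lam``/``A`` broadcast to shape (R,), so each trajectory may
    carry its own parameter set. ``visit(t, P, chosen, gain, loss)`` is
    called once per trial with the pre-choice probabilities (R, 4) and the
    sampled choices/outcomes — callers accumulate whatever they need.
    """
    R, T = U.shape
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (R,))
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (R,))
    A = np.broadcast_to(np.asarray(A, dtype=float), (R,))
    gains, losses = schedule.gains, schedule.losses
    n_cards = schedule.n_cards

    E = np.zeros((R, 4))
    counts = np.zeros((R, 4), dtype=np.int64)
    rows = np.arange(R)
    for t in range(T):
        P = choice_probabilities(E, theta)
        # inverse-CDF sampling from each row's categorical distribution
        c = np.minimum((U[:, t, None] >= np.cumsum(P, axis=1)).sum(axis=1), 3)
        counts[rows, c] += 1
        pos = (counts[rows, c] - 1) % n_cards
        g = gains[c, pos]
        l = losses[c, pos]
        u = pu_utility(g + l, alpha, lam)
        visit(t, P, c, g, l)
        if rule == "DEL":
            E[rows, c] += A * (u - E[rows, c])
        elif rule == "DRI":
            E *= A[:, None]
            E[rows, c] += u
        else:  # pragma: no cover - ParameterSet already validates
            raise ValueError(f"unknown learning rule: {rule!r}")


def simulate_game(
    params: ParameterSet,
    schedule: PayoffSchedule,
    n_trials: int = 100,
    seed=None,
    subject_id=1,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Let the model play ``n_trials`` of the task.

    Returns ``(records, probs)``: a trial-record table with columns
    ``subject_id,trial,deck,gain,loss,net`` and the (n_trials, 4)
    pre-choice prediction matrix. Reproducible from ``seed`` (an int,
    ``SeedSequence`` or ``Generator``).
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    U = np.random.default_rng(seed).random(n_trials)[None, :]
    probs = np.empty((n_trials, 4))
    choices = np.empty(n_trials, dtype=np.int64)
    gain = np.empty(n_trials)
    loss = np.empty(n_trials)

    def visit(t, P, c, g, l):
        probs[t] = P[0]
        choices[t] = c[0]
        gain[t] = g[0]
        loss[t] = l[0]

    _run_paths(params.alpha, params.lam, params.A, params.rule, params.theta, schedule, U, visit)
    records = pd.DataFrame(
        {
            "subject_id": subject_id,
            "trial": np.arange(1, n_trials + 1),
            "deck": [DECKS[c] for c in choices],
            "gain": gain,
            "loss": loss,
            "net": gain + loss,
        }
    )
    return records, probs


def average_simulations(
    params: ParameterSet,
    schedule: PayoffSchedule,
    n_trials: int = 100,
    n_reps: int = 100,
    seed=None,
) -> np.ndarray:
    """Mean prediction matrix over ``n_reps`` independent simulated games.

    Repetition r runs on the r-th child seed of ``seed``; with
    ``n_reps=1`` the result equals the single trajectory
    ``simulate_game(..., seed=SeedSequence(seed).spawn(1)[0])``.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    U = rep_uniforms(seed, n_reps, n_trials)
    total = np.zeros((n_trials, 4))

    def visit(t, P, c, g, l):
        total[t] += P.mean(axis=0)

    _run_paths(params.alpha, params.lam, params.A, params.rule, params.theta, schedule, U, visit)
    return total


def _observed_arrays(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Validate a single subject's trial records; return (deck indices, nets)."""
    if trials is None or len(trials) == 0:
        raise ValueError("trials must be a nonempty trial-record table")
    idx = trials["trial"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ValueError("trial indices must be consecutive from 1 (malformed data)")
    decks = np.array([deck_index(d) for d in trials["deck"]])
    if "net" in trials.columns:
        nets = trials["net"].to_numpy(dtype=float)
    else:
        nets = trials["gain"].to_numpy(dtype=float) + trials["loss"].to_numpy(dtype=float)
    return decks, nets


def one_step_ahead(params: ParameterSet, trials: pd.DataFrame) -> np.ndarray:
    """Replay one subject's observed trials; predict each trial before seeing it.

    ``trials`` is a trial-record table (columns ``trial,deck`` and either
    ``net`` or ``gain``+``loss``) for a single subject, consecutively
    indexed from 1. Row t of the result is the model's deck probabilities
    given the observed history of trials 1..t-1; row 1 is uniform.
    Deterministic — learning is driven entirely by the empirical data.
    """
    decks, nets = _observed_arrays(trials)
    probs = one_step_ahead_batch(
        np.array([params.alpha]),
        np.array([params.lam]),
        np.array([params.A]),
        params.rule,
        params.theta,
        decks,
        nets,
    )
    return probs[0]


def one_step_ahead_batch(
    alpha: np.ndarray,
    lam: np.ndarray,
    A: np.ndarray,
    rule: str,
    theta: float,
    decks: np.ndarray,
    nets: np.ndarray,
) -> np.ndarray:
    """One-step-ahead predictions for B parameter sets at once: (B, T, 4)."""
    B = len(alpha)
    T = len(decks)
    E = np.zeros((B, 4))
    probs = np.empty((B, T, 4))
    for t in range(T):
        probs[:, t] = choice_probabilities(E, theta)
        u = pu_utility(nets[t], alpha, lam)
        j = decks[t]
        if rule == "DEL":
            E[:, j] += A * (u - E[:, j])
        elif rule == "DRI":
            E *= A[:, None]
            E[:, j] += u
        else:  # pragma: no cover
            raise ValueError(f"unknown learning rule: {rule!r}")
    return probs
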