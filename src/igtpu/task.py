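"""Iowa Gambling Task payoff economy.

The task presents four decks of cards. Every pick pays a gain and possibly a
concurrent loss. Decks A and B are "bad": over any aligned run of 10 cards
they net −$250. Decks C and D are "good": +$250 per 10 cards. Orthogonally,
A and C lose frequently (5 losing cards per 10) while B and D lose rarely
(1 per 10) — the gain-loss *frequency* axis that drives the prominent-deck-B
phenomenon in healthy players.

The canonical schedule follows the original Bechara et al. four-deck table:
one 10-card cycle per deck, tiled to 40 cards. It ships as an editable CSV
(``data/bechara_schedule.csv``) so alternate task dialects can be swapped in;
any loaded schedule is validated against the per-cycle net and loss-count
invariants above.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

DECKS: tuple[str, ...] = ("A", "B", "C", "D")

CYCLE_LENGTH = 10
N_CYCLES = 4

#: per-deck invariants of the classic task, per aligned 10-card cycle
CYCLE_NET = {"A": -250.0, "B": -250.0, "C": 250.0, "D": 250.0}
CYCLE_LOSS_COUNT = {"A": 5, "B": 1, "C": 5, "D": 1}
CARD_GAIN = {"A": 100.0, "B": 100.0, "C": 50.0, "D": 50.0}


class ScheduleError(ValueError):
    """Raised when a payoff table violates the task's gain-loss structure."""


def deck_index(deck: str) -> int:
    """Map a deck label (``'A'``–``'D'``) to its array index, or raise."""
    try:
        return DECKS.index(deck)
    except ValueError:
        raise ValueError(f"unknown deck label: {deck!r} (expected one of {DECKS})") from None


@dataclass(frozen=True)
class PayoffSchedule:
    """Per-deck ordered card sequences of (gain, loss).

    ``gains`` and ``losses`` are ``(4, 40)`` arrays indexed ``[deck, position]``
    in deck order A–D. Positions beyond the sequence end wrap to the start
    (card stacks are recycled; depletion is not modelled). Instances are
    validated on construction, so every live schedule satisfies the task
    invariants.
    """

    gains: np.ndarray
    losses: np.ndarray

    def __post_init__(self) -> None:
        gains = np.asarray(self.gains, dtype=float)
        losses = np.asarray(self.losses, dtype=float)
        object.__setattr__(self, "gains", gains)
        object.__setattr__(self, "losses", losses)
        _validate(gains, losses)

    @property
    def n_cards(self) -> int:
        return self.gains.shape[1]

    def card(self, deck: str, draw_count: int) -> tuple[float, float]:
        """The (gain, loss) of the ``draw_count``-th pick from ``deck`` (1-based)."""
        if draw_count < 1:
            raise ValueError(f"draw_count must be >= 1, got {draw_count}")
        i = deck_index(deck)
        pos = (draw_count - 1) % self.n_cards
        return float(self.gains[i, pos]), float(self.losses[i, pos])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns ``deck,position,gain,loss``."""
        rows = [
            (deck, pos + 1, self.gains[i, pos], self.losses[i, pos])
            for i, deck in enumerate(DECKS)
            for pos in range(self.n_cards)
        ]
        return pd.DataFrame(rows, columns=["deck", "position", "gain", "loss"])

    def checksum(self) -> str:
        """SHA-256 of the canonical CSV serialization, for run logging."""
        text = self.to_frame().to_csv(index=False)
        return hashlib.sha256(text.encode()).hexdigest()


def _validate(gains: np.ndarray, losses: np.ndarray) -> None:
    n_cards = CYCLE_LENGTH * N_CYCLES
    if gains.shape != (len(DECKS), n_cards) or losses.shape != (len(DECKS), n_cards):
        raise ScheduleError(
            f"schedule must be {len(DECKS)} decks x {n_cards} cards, "
            f"got gains {gains.shape} / losses {losses.shape}"
        )
    if np.any(gains < 0):
        raise ScheduleError("gains must be >= 0")
    if np.any(losses > 0):
        raise ScheduleError("losses must be <= 0")
    for i, deck in enumerate(DECKS):
        if not np.all(gains[i] == CARD_GAIN[deck]):
            raise ScheduleError(f"deck {deck}: every card must pay a gain of {CARD_GAIN[deck]:g}")
        for c in range(N_CYCLES):
            cyc = slice(c * CYCLE_LENGTH, (c + 1) * CYCLE_LENGTH)
            net = float(np.sum(gains[i, cyc] + losses[i, cyc]))
            if net != CYCLE_NET[deck]:
                raise ScheduleError(
                    f"deck {deck} cycle {c + 1}: net {net:g}, expected {CYCLE_NET[deck]:g}"
                )
            n_loss = int(np.sum(losses[i, cyc] < 0))
            if n_loss != CYCLE_LOSS_COUNT[deck]:
                raise ScheduleError(
                    f"deck {deck} cycle {c + 1}: {n_loss} losing cards, "
                    f"expected {CYCLE_LOSS_COUNT[deck]}"
                )


def build_bechara_schedule() -> PayoffSchedule:
    """The canonical four-deck schedule, loaded from the packaged CSV."""
    ref = resources.files("igtpu").joinpath("data/bechara_schedule.csv")
    with ref.open("r") as fh:
        return load_schedule(fh)


def load_schedule(path_or_buffer) -> PayoffSchedule:
    """Read a ``deck,position,gain,loss`` CSV and validate it.

    Raises :class:`ScheduleError` if the table violates the per-cycle net
    sums, loss counts or fixed per-deck gain amounts.
    """
    df = pd.read_csv(path_or_buffer)
    required = {"deck", "position", "gain", "loss"}
    if not required.issubset(df.columns):
        raise ScheduleError(f"schedule CSV must have columns {sorted(required)}")
    n_cards = CYCLE_LENGTH * N_CYCLES
    gains = np.zeros((len(DECKS), n_cards))
    losses = np.zeros((len(DECKS), n_cards))
    for i, deck in enumerate(DECKS):
        sub = df[df["deck"] == deck].sort_values("position")
        if list(sub["position"]) != list(range(1, n_cards + 1)):
            raise ScheduleError(f"deck {deck}: positions must run 1..{n_cards}")
        gains[i] = sub["gain"].to_numpy()
        losses[i] = sub["loss"].to_numpy()
    return PayoffSchedule(gains=gains, losses=losses)


def save_schedule(schedule: PayoffSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def draw_outcome(schedule: PayoffSchedule, deck: str, draw_count: int) -> tuple[float, float, float]:
    """Deal the ``draw_count``-th card from ``deck``: returns (gain, loss, net).

    Deterministic: a pure function of (deck, draw_count). Positions past the
    end of the 40-card sequence wrap around.
    """
    gain, loss = schedule.card(deck, draw_count)
    return gain, loss, gain + loss
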