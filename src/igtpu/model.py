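"""Valuation and learning machinery of the simplified prospect-utility model.

A chooser values each trial's net payoff x with the prospect-utility (PU)
function

    u(x) = |x|^alpha          if x >= 0
    u(x) = -lambda * |x|^alpha  if x < 0

where ``alpha`` in [0, 1] shapes sensitivity to monetary magnitude and
``lambda`` >= 1 weights losses. Deck expectancies E_j are learned either by
the delta rule (DEL: the chosen deck's expectancy moves a fraction A toward
the current utility) or the decay-reinforcement rule (DRI: all expectancies
decay by factor A and the chosen deck adds the utility). Choices follow a
softmax over expectancies with a fixed sensitivity ``theta``; the
response-consistency parameter of older expectancy-valence models is
deliberately dropped, so the three modulators are alpha, lambda and A alone.

A note on the alpha -> 0 limit: we adopt the convention 0^0 = 1 (IEEE pow,
and what ``numpy`` computes), so at alpha = 0 the utility is a step
function, +1 for any non-negative net and -lambda for any loss. This
matters for deck C, whose losing cards can net exactly zero (gain 50,
loss -50): at alpha = 0 they count as gains. Behaviorally the alpha = 0
chooser is a gain-stay / loss-shift strategist, insensitive to amounts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax as _softmax

from .task import DECKS, deck_index

RULES: tuple[str, ...] = ("DEL", "DRI")

#: the simplified model's optimum: step utility, loss weight 1.3, slow updating
SIMPLIFIED_OPTIMUM = dict(alpha=0.0, lam=1.3, A=0.1, rule="DEL", theta=1.0)


@dataclass(frozen=True)
class ParameterSet:
    """One point in (alpha, lam, A) space plus the learning rule and sensitivity.

    theta is the fixed softmax sensitivity left in place of the removed
    consistency parameter; 1.0 unless deliberately changed.
    """

    alpha: float
    lam: float
    A: float
    rule: str = "DEL"
    theta: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lam < 1.0:
            raise ValueError(f"lam must be >= 1, got {self.lam}")
        if not 0.0 <= self.A <= 1.0:
            raise ValueError(f"A must be in [0, 1], got {self.A}")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")
        if not self.theta > 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")


def simplified_model() -> ParameterSet:
    """The simplified model at its optimized constants (alpha=0, lam=1.3, A=0.1)."""
    return ParameterSet(**SIMPLIFIED_OPTIMUM)


def pu_utility(x, alpha, lam):
    """Prospect utility of a net payoff.

    Accepts scalars or arrays (broadcasting, so ``alpha``/``lam`` may be
    vectors for a batch of parameter sets). Convention 0^0 = 1: at
    alpha = 0 a net of exactly 0 falls in the gain branch with utility 1.
    """
    x = np.asarray(x, dtype=float)
    mag = np.abs(x) ** np.asarray(alpha, dtype=float)
    out = np.where(x >= 0, mag, -np.asarray(lam, dtype=float) * mag)
    return out[()] if out.ndim == 0 else out


def del_update(E, chosen: str, u: float, A: float):
    """Delta-rule step: the chosen deck's expectancy moves fraction A toward u.

    Unchosen decks are untouched. Returns a new array; the input is not
    modified.
    """
    i = deck_index(chosen)
    E = np.array(E, dtype=float, copy=True)
    E[i] += A * (u - E[i])
    return E


def dri_update(E, chosen: str, u: float, A: float):
    """Decay-reinforcement step: every expectancy decays by factor A, the
    chosen deck additionally gains u. Returns a new array."""
    i = deck_index(chosen)
    E = np.array(E, dtype=float, copy=True) * A
    E[i] += u
    return E


def choice_probabilities(E, theta: float = 1.0):
    """Ratio-of-strength softmax over deck expectancies.

    Pr_j = exp(theta * E_j) / sum_k exp(theta * E_k), computed with
    max-subtraction (via ``scipy.special.softmax``) so it is stable for
    large |E|. Works on a length-4 vector or an (..., 4) batch along the
    last axis.
    """
    E = np.asarray(E, dtype=float)
    if not np.all(np.isfinite(E)):
        raise ValueError("expectancies must be finite")
    return _softmax(theta * E, axis=-1)
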