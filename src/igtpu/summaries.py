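"""Descriptive behavioral summaries of a cohort.

Deck-selection means, 20-trial learning blocks, the two classic contrast
scores, and the trial-by-deck choice-probability map. All summaries are
pure functions of the cohort; inferential statistics are deliberately out
of scope — export the tables and test them in your stats package of choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDataset, aggregate_observed
from .task import DECKS


@dataclass
class BlockSummary:
    """Mean per-deck selection counts in consecutive trial blocks.

    ``table`` is blocks x decks (columns A-D); each row of cohort means
    sums to ``block_size``.
    """

    block_size: int
    table: pd.DataFrame


def _counts_by_subject(cohort: CohortDataset) -> pd.DataFrame:
    df = cohort.records
    counts = pd.crosstab(df["subject_id"], df["deck"])
    return counts.reindex(columns=list(DECKS), fill_value=0)


def deck_selection_summary(cohort: CohortDataset) -> pd.Series:
    """Cohort-mean number of picks per deck; sums to trials_per_subject."""
    means = _counts_by_subject(cohort).mean(axis=0)
    means.name = "mean_selections"
    return means


def block_curves(cohort: CohortDataset, block_size: int = 20) -> BlockSummary:
    """Learning curves: mean selections per deck within each trial block."""
    n_trials = cohort.trials_per_subject
    if block_size < 1 or n_trials % block_size != 0:
        raise ValueError(
            f"trials per subject ({n_trials}) must be divisible by block_size ({block_size})"
        )
    df = cohort.records.copy()
    df["block"] = (df["trial"] - 1) // block_size + 1
    counts = pd.crosstab([df["subject_id"], df["block"]], df["deck"]).reindex(
        columns=list(DECKS), fill_value=0
    )
    table = counts.groupby(level="block").mean()
    table.index.name = "block"
    return BlockSummary(block_size=block_size, table=table)


def contrast_scores(summary: BlockSummary | CohortDataset) -> pd.DataFrame:
    """Per-block outcome and gain-frequency learning contrasts.

    outcome   = (C + D) - (A + B): good minus bad decks (long-term payoff).
    frequency = (B + D) - (A + C): frequent-gain minus frequent-loss decks.
    """
    if isinstance(summary, CohortDataset):
        summary = block_curves(summary)
    t = summary.table
    return pd.DataFrame(
        {
            "outcome": (t["C"] + t["D"]) - (t["A"] + t["B"]),
            "frequency": (t["B"] + t["D"]) - (t["A"] + t["C"]),
        }
    )


def choice_probability_map(cohort: CohortDataset) -> pd.DataFrame:
    """Trials x decks choice-proportion map, ready for heatmap rendering.

    Identical content to :func:`igtpu.cohort.aggregate_observed`, exposed
    as a labelled table for export.
    """
    values = aggregate_observed(cohort)
    return pd.DataFrame(
        values, columns=list(DECKS), index=pd.RangeIndex(1, len(values) + 1, name="trial")
    )
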