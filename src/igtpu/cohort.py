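"""Synthetic cohorts and cohort aggregation.

The reference behavioral study collected 145 college students playing 100
scored trials each; that trial-level dataset is not publicly deposited, so
this module generates a stand-in cohort with the statistical structure the
analysis assumes. The default generative agent is the simplified
prospect-utility delta-rule model at its optimized constants (alpha=0,
lam=1.3, A=0.1, theta=1) — the model the study found to reproduce the group
choice pattern, including the hallmark ordering in which bad deck A is
avoided while frequently-gaining decks are preferred.

Every subject is an independent simulated game on a subject-specific child
seed, so cohorts are exactly reproducible and any single subject can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engines import simulate_game
from .model import ParameterSet
from .task import DECKS, PayoffSchedule, deck_index, draw_outcome

#: canonical column order for trial-record tables
COHORT_COLUMNS = ["subject_id", "trial", "deck", "gain", "loss", "net"]


@dataclass
class CohortDataset:
    """Subject-by-trial choice/outcome records plus their provenance.

    ``records`` holds one row per subject x trial with columns
    ``subject_id,trial,deck,gain,loss,net``; ``provenance`` records the
    generator parameters and seed, or ``{"source": "observed"}`` for data
    read from disk.
    """

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_records(self.records)

    @property
    def subject_ids(self) -> list:
        return sorted(self.records["subject_id"].unique())

    @property
    def n_subjects(self) -> int:
        return self.records["subject_id"].nunique()

    @property
    def trials_per_subject(self) -> int:
        counts = self.records.groupby("subject_id").size()
        if counts.nunique() != 1:
            raise ValueError("ragged cohort: subjects have unequal trial counts")
        return int(counts.iloc[0])

    def subject(self, subject_id) -> pd.DataFrame:
        sub = self.records[self.records["subject_id"] == subject_id]
        if len(sub) == 0:
            raise KeyError(f"no such subject: {subject_id!r}")
        return sub.sort_values("trial").reset_index(drop=True)


def validate_records(records: pd.DataFrame) -> None:
    """Structural validation of a trial-record table."""
    missing = set(COHORT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if len(records) == 0:
        raise ValueError("cohort table is empty")
    bad = set(records["deck"]) - set(DECKS)
    if bad:
        raise ValueError(f"unknown deck labels: {sorted(bad)}")
    if not np.allclose(records["net"], records["gain"] + records["loss"], atol=1e-9):
        raise ValueError("net must equal gain + loss on every row")
    for sid, sub in records.groupby("subject_id"):
        t = np.sort(sub["trial"].to_numpy())
        if not np.array_equal(t, np.arange(1, len(t) + 1)):
            raise ValueError(f"subject {sid!r}: trial indices must be consecutive from 1")


def generate_cohort(
    n_subjects: int,
    n_trials: int,
    params: ParameterSet,
    schedule: PayoffSchedule,
    seed=None,
    jitter: float = 0.0,
) -> CohortDataset:
    """Simulate a cohort of independent model-playing subjects.

    Subject i runs :func:`igtpu.engines.simulate_game` on the i-th child of
    ``seed``. ``jitter`` > 0 adds optional between-subject heterogeneity:
    each subject's (alpha, lam, A) is drawn uniformly within ``jitter`` of
    ``params`` and clipped to the valid ranges (off by default — the
    reference model describes the group mean).
    """
    if n_subjects < 1 or n_trials < 1:
        raise ValueError(
            f"n_subjects and n_trials must be >= 1, got {n_subjects} x {n_trials}"
        )
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(n_subjects)
    frames = []
    for i, child in enumerate(children, start=1):
        p = params
        if jitter > 0:
            jrng = np.random.default_rng(child.spawn(1)[0])
            p = ParameterSet(
                alpha=float(np.clip(params.alpha + jrng.uniform(-jitter, jitter), 0, 1)),
                lam=float(np.clip(params.lam + jrng.uniform(-jitter, jitter), 1, np.inf)),
                A=float(np.clip(params.A + jrng.uniform(-jitter, jitter), 0, 1)),
                rule=params.rule,
                theta=params.theta,
            )
        records, _ = simulate_game(p, schedule, n_trials, seed=child, subject_id=i)
        frames.append(records)
    provenance = {
        "source": "synthetic",
        "params": {"alpha": params.alpha, "lam": params.lam, "A": params.A,
                   "rule": params.rule, "theta": params.theta},
        "seed": repr(seed),
        "jitter": jitter,
        "n_subjects": n_subjects,
        "n_trials": n_trials,
    }
    return CohortDataset(records=pd.concat(frames, ignore_index=True), provenance=provenance)


def aggregate_observed(cohort: CohortDataset) -> np.ndarray:
    """Per-trial cross-subject choice proportions: the benchmark matrix.

    Entry (t, j) is the fraction of subjects who chose deck j on trial t
    (deck order A-D); every row sums to 1. Requires all subjects to share
    the same trial count.
    """
    n_trials = cohort.trials_per_subject
    n_subjects = cohort.n_subjects
    counts = np.zeros((n_trials, 4))
    t = cohort.records["trial"].to_numpy() - 1
    j = np.array([deck_index(d) for d in cohort.records["deck"]])
    np.add.at(counts, (t, j), 1.0)
    return counts / n_subjects


def verify_against_schedule(cohort: CohortDataset, schedule: PayoffSchedule) -> None:
    """Check every outcome matches the card at the subject's own draw position.

    Replays each subject's per-deck draw history and confirms the recorded
    (gain, loss) equals what the deck's stack would have dealt. Raises
    ``ValueError`` on the first inconsistency.
    """
    for sid in cohort.subject_ids:
        sub = cohort.subject(sid)
        draws = dict.fromkeys(DECKS, 0)
        for row in sub.itertuples(index=False):
            draws[row.deck] += 1
            gain, loss, _ = draw_outcome(schedule, row.deck, draws[row.deck])
            if gain != row.gain or loss != row.loss:
                raise ValueError(
                    f"subject {sid!r} trial {row.trial}: recorded "
                    f"({row.gain}, {row.loss}) but deck {row.deck} draw "
                    f"{draws[row.deck]} deals ({gain}, {loss})"
                )
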