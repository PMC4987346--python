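"""MSD goodness-of-fit, the exhaustive parameter grid search, and the
top-fraction parameter-frequency analysis.

Model fit is scored by the mean squared deviation (MSD) between a model's
prediction matrix and a *benchmark matrix* — the per-trial, cross-subject
choice proportions of a cohort. Likelihood-product scores are deliberately
not offered: successive IGT choices are not independent, and MSD directly
measures how well a model reproduces the overall choice pattern.

The search is exhaustive over a fixed lattice; the canonical grid crosses
11 alpha values (0..1 by 0.1), 16 lambda values (1.0..2.5 by 0.1) and
11 A values (0..1 by 0.1) — 1936 parameter sets. Each point is scored
either by averaging repeated general simulations (the mean trajectory
against the mean benchmark) or by deterministic one-step-ahead replay of
supplied trial data. All repetitions share the same per-repetition child
seeds across grid points (common random numbers), so differences in MSD
between neighbouring points reflect the parameters, not sampling noise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engines
from .engines import one_step_ahead_batch, rep_uniforms
from .model import RULES, ParameterSet, simplified_model
from .task import PayoffSchedule

logger = logging.getLogger("igtpu")

_SIM_ENGINES = {"sim", "simulation", "general_simulation"}
_OSA_ENGINES = {"osa", "one_step_ahead"}

_PARAM_ALIASES = {
    "alpha": "alpha",
    "lam": "lam",
    "lambda": "lam",
    "A": "A",
    "a": "A",
}


def _round_grid(values) -> tuple[float, ...]:
    return tuple(float(np.round(v, 10)) for v in values)


@dataclass(frozen=True)
class GridSpec:
    """The alpha / lambda / A value lattices of an exhaustive search."""

    alphas: tuple[float, ...]
    lams: tuple[float, ...]
    As: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (self.alphas and self.lams and self.As):
            raise ValueError("grid must have at least one value per parameter")
        object.__setattr__(self, "alphas", _round_grid(self.alphas))
        object.__setattr__(self, "lams", _round_grid(self.lams))
        object.__setattr__(self, "As", _round_grid(self.As))

    def __len__(self) -> int:
        return len(self.alphas) * len(self.lams) * len(self.As)

    def points(self) -> pd.DataFrame:
        """All parameter sets, in lexicographic (alpha, lam, A) order."""
        rows = list(itertools.product(self.alphas, self.lams, self.As))
        return pd.DataFrame(rows, columns=["alpha", "lam", "A"])


def default_grid() -> GridSpec:
    """The canonical 11 x 16 x 11 = 1936-point lattice."""
    return GridSpec(
        alphas=_round_grid(np.arange(0.0, 1.05, 0.1)),
        lams=_round_grid(np.arange(1.0, 2.55, 0.1)),
        As=_round_grid(np.arange(0.0, 1.05, 0.1)),
    )


def compute_msd(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Mean squared deviation between two trials-by-decks matrices.

    The mean runs over all trials *and* all four decks; for probability
    matrices the value lies in [0, 2].
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs observed {observed.shape}"
        )
    return float(np.mean((predicted - observed) ** 2))


def validate_benchmark(benchmark: np.ndarray) -> np.ndarray:
    benchmark = np.asarray(benchmark, dtype=float)
    if benchmark.ndim != 2 or benchmark.shape[1] != 4:
        raise ValueError(f"benchmark must be (n_trials, 4), got {benchmark.shape}")
    if np.any(benchmark < 0) or np.any(benchmark > 1):
        raise ValueError("benchmark entries must lie in [0, 1]")
    if not np.allclose(benchmark.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("benchmark rows must sum to 1")
    return benchmark


@dataclass
class GridResult:
    """MSD scores for every parameter set of a grid search.

    ``table`` has columns ``alpha,lam,A,rule,msd`` in lexicographic grid
    order. Rankings break MSD ties lexicographically by (alpha, lam, A).
    """

    table: pd.DataFrame
    grid: GridSpec
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values(
            ["msd", "alpha", "lam", "A"], kind="stable"
        ).reset_index(drop=True)

    def best(self) -> tuple[ParameterSet, float]:
        """The minimum-MSD parameter set (ties broken by (alpha, lam, A))."""
        row = self.ranked().iloc[0]
        params = ParameterSet(
            alpha=float(row["alpha"]), lam=float(row["lam"]), A=float(row["A"]),
            rule=str(row["rule"]),
        )
        return params, float(row["msd"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def grid_search(
    benchmark: np.ndarray,
    grid: GridSpec,
    rule: str = "DEL",
    engine: str = "simulation",
    schedule: PayoffSchedule | None = None,
    n_reps: int = 100,
    seed=None,
    trials: pd.DataFrame | None = None,
    theta: float = 1.0,
) -> GridResult:
    """Score every grid point against a benchmark matrix.

    engine="simulation": each point is scored by the MSD of its mean
    simulated trajectory (``n_reps`` repetitions, common random numbers
    across points) against the benchmark; requires ``schedule``.
    engine="one_step_ahead": each point deterministically replays
    ``trials`` (one subject's records, or a full cohort whose per-subject
    prediction matrices are averaged); no schedule or repetitions needed.
    """
    benchmark = validate_benchmark(benchmark)
    if len(grid) == 0:
        raise ValueError("empty parameter grid")
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}, got {rule!r}")
    points = grid.points()
    alphas = points["alpha"].to_numpy()
    lams = points["lam"].to_numpy()
    As = points["A"].to_numpy()
    n_trials = benchmark.shape[0]

    if engine in _SIM_ENGINES:
        if schedule is None:
            raise ValueError("the simulation engine requires a payoff schedule")
        msd = _grid_msd_simulation(
            alphas, lams, As, rule, theta, schedule, benchmark, n_reps, seed
        )
        logger.info(
            "grid_search engine=simulation rule=%s points=%d n_reps=%d seed=%r "
            "schedule=%s",
            rule, len(points), n_reps, seed, schedule.checksum()[:12],
        )
    elif engine in _OSA_ENGINES:
        if trials is None:
            raise ValueError("the one-step-ahead engine requires observed trial data")
        msd = _grid_msd_osa(alphas, lams, As, rule, theta, trials, benchmark)
        logger.info(
            "grid_search engine=one_step_ahead rule=%s points=%d", rule, len(points)
        )
    else:
        raise ValueError(f"unknown engine: {engine!r}")

    table = points.assign(rule=rule, msd=msd)
    meta = {"engine": engine, "rule": rule, "n_reps": n_reps, "seed": seed,
            "n_trials": n_trials}
    return GridResult(table=table, grid=grid, meta=meta)


def _grid_msd_simulation(
    alphas, lams, As, rule, theta, schedule, benchmark, n_reps, seed
) -> np.ndarray:
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    B = len(alphas)
    n_trials = benchmark.shape[0]
    U_rep = rep_uniforms(seed, n_reps, n_trials)
    U = np.tile(U_rep, (B, 1))  # trajectory r of point b reuses rep r's draws
    sse = np.zeros(B)

    def visit(t, P, c, g, l):
        mean_t = P.reshape(B, n_reps, 4).mean(axis=1)
        sse[:] += ((mean_t - benchmark[t]) ** 2).sum(axis=1)

    engines._run_paths(
        np.repeat(alphas, n_reps), np.repeat(lams, n_reps), np.repeat(As, n_reps),
        rule, theta, schedule, U, visit,
    )
    return sse / (n_trials * 4)


def _grid_msd_osa(alphas, lams, As, rule, theta, trials, benchmark) -> np.ndarray:
    if "subject_id" in trials.columns and trials["subject_id"].nunique() > 1:
        groups = [g for _, g in trials.groupby("subject_id", sort=True)]
    else:
        groups = [trials]
    total = np.zeros((len(alphas), benchmark.shape[0], 4))
    for g in groups:
        decks, nets = engines._observed_arrays(g.reset_index(drop=True))
        if len(decks) != benchmark.shape[0]:
            raise ValueError("trial data length must match the benchmark")
        total += one_step_ahead_batch(alphas, lams, As, rule, theta, decks, nets)
    mean = total / len(groups)
    return ((mean - benchmark[None]) ** 2).mean(axis=(1, 2))


def top_fraction_counts(
    result: GridResult, fraction: float, parameter: str
) -> pd.Series:
    """Frequency of a parameter's values among the best-fitting grid points.

    Selects the ``ceil(fraction * N)`` lowest-MSD entries (e.g. 10% of the
    1936-point grid -> 194 entries) and tabulates how often each lattice
    value of ``parameter`` ('alpha', 'lam'/'lambda' or 'A') appears — the
    diagnostic that shows which parameters actually steer the fit.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(result) == 0:
        raise ValueError("empty grid result")
    key = _PARAM_ALIASES.get(parameter)
    if key is None:
        raise ValueError(f"parameter must be one of {sorted(_PARAM_ALIASES)}")
    k = math.ceil(fraction * len(result))
    top = result.ranked().head(k)
    values = {"alpha": result.grid.alphas, "lam": result.grid.lams,
              "A": result.grid.As}[key]
    counts = top[key].value_counts().reindex(values, fill_value=0).astype(int)
    counts.index.name = key
    counts.name = "count"
    return counts


def compare_rules(
    benchmark: np.ndarray,
    grid: GridSpec,
    engine: str = "simulation",
    schedule: PayoffSchedule | None = None,
    n_reps: int = 100,
    seed=None,
    trials: pd.DataFrame | None = None,
    theta: float = 1.0,
) -> dict[str, tuple[ParameterSet, float]]:
    """Best (parameter set, MSD) per learning rule, from one grid search each.

    Both rules are scored with the same seed (hence the same repetition
    draws), so the comparison mirrors running the two models on identical
    benchmarks.
    """
    out: dict[str, tuple[ParameterSet, float]] = {}
    for rule in RULES:
        res = grid_search(
            benchmark, grid, rule=rule, engine=engine, schedule=schedule,
            n_reps=n_reps, seed=seed, trials=trials, theta=theta,
        )
        out[rule] = res.best()
    return out


def recover_parameters(
    seed,
    schedule: PayoffSchedule,
    generating: ParameterSet | None = None,
    n_subjects: int = 145,
    n_trials: int = 100,
    grid: GridSpec | None = None,
    rule: str = "DEL",
    n_reps: int = 400,
    theta: float = 1.0,
) -> GridResult:
    """End-to-end parameter-recovery experiment.

    Generates a synthetic cohort from ``generating`` (default: the
    simplified model at alpha=0, lam=1.3, A=0.1), aggregates it to a
    benchmark, and runs the exhaustive grid search with the simulation
    engine. The cohort and search seeds are derived from one root seed.

    ``n_reps`` defaults to 400 here (vs the grid-search default of 100):
    the recovery question is whether the *benchmark* pins down the
    generating point, so the scorer's own Monte-Carlo error is budgeted
    well below the cohort's sampling error. See the methods note.
    """
    from .cohort import aggregate_observed, generate_cohort  # avoid import cycle

    if generating is None:
        generating = simplified_model()
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(seed)
    cohort_seed, search_seed = (int(s) for s in rng.integers(0, 2**31, size=2))
    cohort = generate_cohort(n_subjects, n_trials, generating, schedule, seed=cohort_seed)
    benchmark = aggregate_observed(cohort)
    result = grid_search(
        benchmark, grid, rule=rule, engine="simulation", schedule=schedule,
        n_reps=n_reps, seed=search_seed, theta=theta,
    )
    result.meta.update(
        {"experiment": "parameter_recovery", "root_seed": seed,
         "n_subjects": n_subjects, "generating": generating}
    )
    return result
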