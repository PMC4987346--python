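"""Plain-text I/O for cohorts, benchmarks and grid results, plus run
configuration and logging helpers.

All tabular exchange formats are CSV:

* cohort / trial records: ``subject_id,trial,deck,gain,loss,net``
* benchmark or prediction matrices: ``trial,A,B,C,D``
* grid-search results: ``alpha,lam,A,rule,msd``

Loaders validate structural invariants (consecutive trials, rows summing
to 1) and raise on malformed files rather than propagating bad data.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, CohortDataset
from .fitting import GridResult, GridSpec, validate_benchmark
from .task import DECKS

logger = logging.getLogger("igtpu")


def write_cohort(cohort: CohortDataset, path) -> None:
    cohort.records[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> CohortDataset:
    """Read a trial-record CSV; validation happens in ``CohortDataset``."""
    records = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return CohortDataset(records=records, provenance={"source": "observed", "path": str(path)})


def write_matrix(matrix, path) -> None:
    """Write a trials x decks probability/proportion matrix as trial,A,B,C,D."""
    values = np.asarray(matrix, dtype=float)
    df = pd.DataFrame(values, columns=list(DECKS))
    df.insert(0, "trial", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False)


def read_matrix(path) -> np.ndarray:
    """Read a trial,A,B,C,D matrix CSV and validate it as a benchmark."""
    df = pd.read_csv(path)
    missing = set(DECKS) - set(df.columns)
    if missing:
        raise ValueError(f"matrix CSV missing deck columns: {sorted(missing)}")
    if "trial" in df.columns:
        df = df.sort_values("trial")
    return validate_benchmark(df[list(DECKS)].to_numpy(dtype=float))


def write_grid_result(result: GridResult, path) -> None:
    result.to_csv(path)


def read_grid_result(path) -> GridResult:
    table = pd.read_csv(path)
    required = {"alpha", "lam", "A", "rule", "msd"}
    if not required.issubset(table.columns):
        raise ValueError(f"grid-result CSV must have columns {sorted(required)}")
    grid = GridSpec(
        alphas=tuple(sorted(table["alpha"].unique())),
        lams=tuple(sorted(table["lam"].unique())),
        As=tuple(sorted(table["A"].unique())),
    )
    return GridResult(table=table, grid=grid, meta={"source": str(path)})


def load_config(path) -> dict:
    """Read a flat JSON key-value configuration file."""
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a JSON object")
    return cfg


def configure_logging(level=logging.INFO) -> None:
    """Attach a simple stderr handler to the package logger (idempotent)."""
    log = logging.getLogger("igtpu")
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s igtpu %(message)s"))
        log.addHandler(handler)
    log.setLevel(level)
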