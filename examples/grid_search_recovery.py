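"""Fit the full 1936-point parameter grid to a synthetic benchmark.

Generates a cohort from the simplified model (alpha=0, lam=1.3, A=0.1),
aggregates it into a per-trial choice-proportion benchmark, scores every
(alpha, lambda, A) lattice point by the MSD of its mean simulated
trajectory, and tabulates which alpha values dominate the best-fitting 10%.
Uses 50 simulation repetitions per point to stay quick; the headline
recovery experiment in scripts/acceptance.py uses 400. Run:

    python examples/grid_search_recovery.py
"""

import igtpu

schedule = igtpu.build_bechara_schedule()
generating = igtpu.simplified_model()

cohort = igtpu.generate_cohort(145, 100, generating, schedule, seed=5)
benchmark = igtpu.aggregate_observed(cohort)

result = igtpu.grid_search(
    benchmark, igtpu.default_grid(), rule="DEL", engine="simulation",
    schedule=schedule, n_reps=50, seed=6,
)
best, msd = result.best()
print(f"scored {len(result)} grid points")
print(f"generating model: alpha=0  lam=1.3  A=0.1")
print(f"minimum-MSD point: alpha={best.alpha:g}  lam={best.lam:g}  A={best.A:g}  (MSD {msd:.6f})")

counts = igtpu.top_fraction_counts(result, fraction=0.10, parameter="alpha")
print(f"\nalpha frequencies in the best-fitting 10% ({counts.sum()} points):")
print(counts.to_string())
print(
    "\nThe search lands on (or next to) the generating point, and small "
    "alpha values crowd the top decile: with a step-like utility the fit "
    "is driven by gain-loss frequency, so alpha is pinned near zero while "
    "lambda and A matter less."
)
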