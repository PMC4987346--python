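import numpy as np
import pytest

import igtpu


@pytest.fixture(scope="session")
def schedule():
    return igtpu.build_bechara_schedule()


@pytest.fixture(scope="session")
def simplified():
    """The simplified model at its optimized constants."""
    return igtpu.simplified_model()


@pytest.fixture(scope="session")
def small_cohort(schedule, simplified):
    """A 12-subject, 40-trial synthetic cohort for structural tests."""
    return igtpu.generate_cohort(12, 40, simplified, schedule, seed=11)


@pytest.fixture(scope="session")
def manual_cohort(schedule):
    """Factory: build a valid cohort where each subject picks a fixed deck
    string (outcomes dealt from the schedule at the subject's own draw
    positions)."""
    import pandas as pd

    from igtpu.cohort import CohortDataset

    def build(decks_by_subject):
        frames = []
        for sid, decks in enumerate(decks_by_subject, start=1):
            draws = dict.fromkeys("ABCD", 0)
            rows = []
            for t, d in enumerate(decks, start=1):
                draws[d] += 1
                g, l, net = igtpu.draw_outcome(schedule, d, draws[d])
                rows.append((sid, t, d, g, l, net))
            frames.append(
                pd.DataFrame(
                    rows, columns=["subject_id", "trial", "deck", "gain", "loss", "net"]
                )
            )
        return CohortDataset(records=pd.concat(frames, ignore_index=True))

    return build


@pytest.fixture(scope="session")
def canonical_grid_result(schedule, simplified):
    """A full 1936-point grid result, scored cheaply with one-step-ahead
    replay of a single simulated subject (structure tests only)."""
    records, _ = igtpu.simulate_game(simplified, schedule, n_trials=30, seed=21)
    bench = igtpu.aggregate_observed(
        igtpu.CohortDataset(records=records, provenance={"source": "synthetic"})
    )
    return igtpu.grid_search(
        bench, igtpu.default_grid(), rule="DEL", engine="one_step_ahead", trials=records
    )
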