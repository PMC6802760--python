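import numpy as np
import pandas as pd
import pytest

import visualspan as vs


@pytest.fixture(scope="session")
def design():
    return vs.default_design()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete simulated experiment (4 per group, seeded)."""
    cfg = vs.default_config(n_per_group=4)
    participants, trials, reading = vs.simulate_experiment(cfg, seed=1234)
    return cfg, participants, trials, reading


@pytest.fixture(scope="session")
def one_participant_trials(design):
    """Deterministic all-correct session for one participant, one complexity."""
    rows = []
    for block in range(design.blocks_per_level):
        for center in design.center_positions:
            for _ in range(design.reps_per_center_per_block):
                rows.append(("p1", "young", "low", block, center,
                             1, 2, 3, True, True, True))
    return pd.DataFrame(rows, columns=vs.design.TRIAL_COLUMNS)


def make_span_table(rng, n_per_group=5, means=None, sd=1.0):
    """Random balanced long-format span table for ANOVA tests."""
    means = means or {}
    rows = []
    for group in ("young", "older"):
        for i in range(n_per_group):
            pid = f"{group}{i:02d}"
            for comp in ("low", "medium", "high"):
                mu = means.get((group, comp), 5.0)
                rows.append((pid, group, comp, rng.normal(mu, sd)))
    return pd.DataFrame(rows, columns=["participant_id", "age_group",
                                       "complexity", "span"])
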