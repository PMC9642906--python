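import numpy as np
import pandas as pd
import pytest

import trajclust as tc


@pytest.fixture(scope="session")
def small_study():
    """A simulated 200-participant study shared across read-only tests."""
    return tc.simulate_study(n_participants=200, seed=11)


@pytest.fixture(scope="session")
def small_run(small_study):
    """Full pipeline results on the small study (k=3, short sweep)."""
    cfg = tc.AnalysisConfig(k=3, k_range=[1, 2, 3, 4, 5], seed=7)
    return tc.run_analysis(
        small_study["visits"], small_study["labs"], small_study["sti"],
        small_study["participants"], config=cfg,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)


def make_visits(rows):
    """Helper: build a visit table from (pid, date, a, b, c) tuples."""
    return pd.DataFrame(
        rows, columns=["participant_id", "visit_date", "ans_nsP",
                       "ans_intercourse", "ans_condom_always"],
    )
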