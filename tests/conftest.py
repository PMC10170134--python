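import numpy as np
import pandas as pd
import pytest

from ownflow.data_model import CONDITIONS, RH_SYNC, TRIAL_LEN_S, read_ratings
from ownflow.synthetic import CohortConfig, generate_study


def ratings_frame(per_participant: dict) -> pd.DataFrame:
    """Long-format ratings table from {pid: {condition: ratings array}}."""
    rows = []
    for pid, conds in per_participant.items():
        for cond, ratings in conds.items():
            for t, r in enumerate(ratings, start=1):
                rows.append((pid, cond, t, r))
    return pd.DataFrame(
        rows, columns=["participant_id", "condition", "time_s", "rating"]
    )


def constant_study(n_participants: int = 2, value: float = 100.0):
    """Dataset where every series is a constant."""
    per = {
        f"p{i:02d}": {c: np.full(TRIAL_LEN_S, value) for c in CONDITIONS}
        for i in range(1, n_participants + 1)
    }
    return read_ratings(ratings_frame(per))


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant synthetic study with default calibration (seeded)."""
    return generate_study(n_participants=12, master_seed=42)


@pytest.fixture(scope="session")
def planted_cohort():
    """27 responders + 3 non-responders, breakpoints fixed at 19/87 s."""
    cfg = CohortConfig(
        n_participants=30, onset_log_sd=0.0, plateau_sd_s=0.0
    )
    return generate_study(config=cfg, master_seed=7)
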