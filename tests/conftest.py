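import numpy as np
import pandas as pd
import pytest

from rewardbias.simulate import generate_fixture


@pytest.fixture(scope="session")
def null_study():
    """One small null study (no stimulation or mood effects), shared across tests."""
    return generate_fixture("null", seed=20240611)


@pytest.fixture(scope="session")
def null_results(null_study):
    from rewardbias.study import RewardResponsivenessStudy

    study = RewardResponsivenessStudy.from_frames(
        null_study.trials, null_study.questionnaires
    )
    return study.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(987)


def make_trials(rows):
    """Small trial-log frames from compact dicts with schema defaults."""
    defaults = {
        "participant_id": "p01", "session": 1, "stimulation": "active",
        "phase": "post", "block": 1, "trial": 1, "stimulus": "long",
        "role": "rich", "response": "long", "correct": 1, "rewarded": 0,
        "rt_ms": 500.0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["trial"] = i % 100 + 1
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)
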