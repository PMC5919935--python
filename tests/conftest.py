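import numpy as np
import pandas as pd
import pytest

from moodchoice import synthetic


def make_table(feedback, accuracy=0.6, **extra):
    """Minimal trial table from a feedback sequence."""
    n = len(feedback)
    base = {
        "session": np.zeros(n, dtype=int),
        "trial": np.arange(1, n + 1),
        "difficulty": ["medium"] * n,
        "accuracy_mean": np.full(n, accuracy, dtype=float),
        "correct": (np.asarray(feedback) > 0).astype(int),
        "feedback": np.asarray(feedback, dtype=int),
        "gain": np.ones(n),
        "loss": np.ones(n),
        "size": np.full(n, 0.1),
        "choice": np.zeros(n),
        "mood_rating": np.full(n, np.nan),
        "confidence_rating": np.full(n, np.nan),
    }
    base.update(extra)
    return pd.DataFrame(base)


@pytest.fixture(scope="session")
def default_agent():
    """One simulated agent under the default study conditions."""
    truth = synthetic.draw_ground_truth(
        synthetic.default_truth_distribution(), seed=2024)
    table = synthetic.simulate_agent(synthetic.TaskConfig(seed=7), truth)
    return table, truth
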