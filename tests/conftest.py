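import numpy as np
import pandas as pd
import pytest


def make_trials(true_alt, response, confidence):
    """Build a minimal trial table from parallel sequences."""
    true_alt = list(true_alt)
    response = list(response)
    return pd.DataFrame(
        {
            "true_alt": true_alt,
            "response": response,
            "correct": [t == r for t, r in zip(true_alt, response)],
            "confidence": list(confidence),
        }
    )


def random_trials(rng, n, p_correct=0.75, conf_informative=True):
    """Random confidence-rated trial set (not from the package's simulator)."""
    true_alt = np.where(rng.random(n) < 0.5, "A", "B")
    correct = rng.random(n) < p_correct
    response = np.where(correct, true_alt, np.where(true_alt == "A", "B", "A"))
    if conf_informative:
        conf = np.where(correct, rng.integers(2, 5, n), rng.integers(1, 4, n))
    else:
        conf = rng.integers(1, 5, n)
    return pd.DataFrame(
        {
            "true_alt": true_alt,
            "response": response,
            "correct": correct,
            "confidence": conf.astype(int),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
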