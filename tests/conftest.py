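import numpy as np
import pandas as pd
import pytest

from metaselect import Dataset, SynthSpec, dataset_from_frame, generate_survey
from metaselect.data import NEGATIVE, POSITIVE


def make_labeled_ds(n_pos, n_neg, seed=0, n_features=1):
    """Minimal labelled dataset with noise features, for split/fold tests."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    frame = pd.DataFrame(
        {f"x{j}": rng.standard_normal(n) for j in range(n_features)}
    )
    labels = np.array([POSITIVE] * n_pos + [NEGATIVE] * n_neg, dtype=object)
    rng.shuffle(labels)
    return dataset_from_frame(frame, labels=labels, classes=[POSITIVE, NEGATIVE])


@pytest.fixture
def tiny_mixed_ds():
    """20 instances, 3 features (nominal, numeric, nominal-with-missing)."""
    rng = np.random.default_rng(42)
    n = 20
    frame = pd.DataFrame({
        "color": rng.choice(["red", "blue", "green"], n).astype(object),
        "age": rng.normal(60, 8, n),
        "smoker": rng.choice(["yes", "no"], n).astype(object),
    })
    frame.loc[3, "smoker"] = np.nan
    frame.loc[7, "age"] = np.nan
    labels = np.array(
        [POSITIVE if i % 2 == 0 else NEGATIVE for i in range(n)], dtype=object
    )
    return dataset_from_frame(frame, labels=labels, classes=[POSITIVE, NEGATIVE])


@pytest.fixture(scope="session")
def small_survey():
    """Small synthetic survey with planted signal, shared across tests."""
    spec = SynthSpec(
        n_instances=300, n_positive=120, n_features=15, n_informative=4,
        effect=0.4, missing_rate=0.05, seed=7,
    )
    return generate_survey(spec)
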