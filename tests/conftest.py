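import numpy as np
import pandas as pd
import pytest

import iatkit as ik


def make_table(
    n_subjects=4,
    practice=4,
    test=8,
    seed=0,
    built_in=False,
    error_rate=0.1,
):
    """Tiny hand-rolled trial table (independent of the synthetic module)
    for unit tests that just need valid structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for pairing in ("compatible", "incompatible"):
            shift = 100.0 if pairing == "incompatible" else 0.0
            for phase, n in (("practice", practice), ("test", test)):
                lat = rng.gamma(8, 80, n) + 250 + shift
                err = rng.random(n) < error_rate
                for t in range(n):
                    rows.append(
                        (f"subj{s}", 1, pairing, phase, float(lat[t]), bool(err[t]))
                    )
    df = pd.DataFrame(
        rows,
        columns=["subject", "session", "pairing", "phase", "latency_ms", "error"],
    )
    return ik.TrialTable(df, built_in_penalty=built_in, dataset_label="fixture")


@pytest.fixture
def small_table():
    return make_table()


@pytest.fixture
def standard_table():
    """20 practice + 40 test trials per pairing, the classic critical-block
    layout."""
    return make_table(n_subjects=3, practice=20, test=40, seed=1)
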