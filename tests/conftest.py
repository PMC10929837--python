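import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ucquant as uq

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_cohorts():
    """Four cohorts sharing one planted truth: one for training, three held out."""
    spec = uq.SimSpec(n_genes=300, n_case=40, n_control=40, n_up=30, n_down=30,
                      effect_lfc=2.0, noise_sd=0.5, n_cohorts=4, seed=11)
    return uq.simulate_cohorts(spec)


@pytest.fixture(scope="session")
def train_cohort(planted_cohorts):
    return planted_cohorts[0]


@pytest.fixture(scope="session")
def planted_panel(train_cohort):
    _, truth = train_cohort
    return uq.SignaturePanel(
        [(g, 1) for g in truth["up_genes"][:6]] + [(g, -1) for g in truth["down_genes"][:6]]
    )


@pytest.fixture
def tiny_expr():
    """3 genes x 4 samples, two groups, hand-checkable values."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [2.0, 2.0, 2.0, 2.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    ann = pd.DataFrame({"group": ["case", "case", "control", "control"]},
                       index=values.columns)
    return uq.ExpressionMatrix(values, ann)


def jaccard(a, b):
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)
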