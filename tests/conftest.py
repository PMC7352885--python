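import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import baxloc as bl

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def clean_config():
    """Noise-free study-scale cohort: every stochastic layer switched off so
    rendered blots are an exact linear image of the ground truth (per-blot
    gains still vary)."""
    return bl.CohortConfig(noise_sd_log10=0.0, loading_sd_log10=0.0, seed=11)


@pytest.fixture
def clean_truth(clean_config):
    return bl.simulate_cohort(clean_config)


@pytest.fixture
def clean_lanes(clean_config, clean_truth):
    return bl.render_blots(clean_truth.tissues, clean_config)


def pipeline_deltas(config: "bl.CohortConfig", threshold=-1.0):
    """render -> calibrate (through origin) -> score -> classify, returning
    (calls, truth); the scoring path never touches hidden truth."""
    truth = bl.simulate_cohort(config)
    lanes = bl.render_blots(truth.tissues, config)
    amounts = bl.calibrate_lanes(lanes, through_origin=True)
    loc = bl.score_localization(bl.marker_normalize(amounts))
    calls, _ = bl.classify_protection(loc, threshold)
    return calls, truth


@pytest.fixture
def expression_small():
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(4, 3),
        index=list("abcd"), columns=["s1", "s2", "s3"])
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    return bl.ExpressionMatrix(values=values, mask=mask)
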