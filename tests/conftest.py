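"""Shared fixtures: a synthetic corpus, its feature table, and a classifier.

The heavy artifacts (a 50-per-class corpus pushed through the full image
chain) are session-scoped so the pipeline and acceptance tests share one
computation.
"""

import numpy as np
import pytest

import teledermo as td
from teledermo import classify, pipeline

CORPUS_SEED = 11
N_PER_CLASS = 50


@pytest.fixture(scope="session")
def corpus():
    """50 synthetic lesions per class (200 images)."""
    return td.generate_class_set(N_PER_CLASS, seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def corpus_table(corpus):
    """Raw feature table via the full hair-removal/segmentation chain."""
    table, scaler, skipped = pipeline.corpus_features(corpus)
    assert not skipped, f"segmentation failed on samples {skipped}"
    return table, scaler


@pytest.fixture(scope="session")
def scaled_table(corpus_table):
    table, scaler = corpus_table
    return pipeline.scale_table(table, scaler), scaler


@pytest.fixture(scope="session")
def model(scaled_table):
    table, scaler = scaled_table
    return classify.train(table, seed=0, scaler=scaler)


@pytest.fixture(scope="session")
def carrier():
    """22,000-sample speech-like carrier at 8 kHz."""
    return pipeline.default_carrier(n_samples=22000, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dps(n, rng, lo=0.05, hi=0.95):
    """Helper: n random valid DPs."""
    from teledermo import profile

    return [profile.build_dp(rng.uniform(lo, hi, 7), f"dp{k}")
            for k in range(n)]
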