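"""Shared fixtures: small synthetic cohorts and their feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from restalpha.montage import CLUSTER_14_MONTAGE
from restalpha.pipeline import features_table
from restalpha.simulate import default_group_configs, generate_cohort


@pytest.fixture(scope="session")
def default_configs():
    return default_group_configs()


@pytest.fixture(scope="session")
def small_cohort(default_configs):
    """8 subjects per group, minimal montage, truth components attached."""
    hsg, lsg = default_configs
    recordings, truth = generate_cohort(
        hsg, lsg, n_per_group=8, seed=0, montage=CLUSTER_14_MONTAGE,
        keep_truth_components=True,
    )
    return recordings, truth


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    recordings, truth = small_cohort
    feats = features_table(recordings, mode="backprojection")
    return feats, truth


@pytest.fixture(scope="session")
def random_feature_table():
    """Uninformative (null) feature table: features independent of labels."""
    from restalpha.classify import FEATURE_NAMES

    rng = np.random.default_rng(12345)
    df = pd.DataFrame(rng.standard_normal((48, 14)), columns=FEATURE_NAMES)
    df["group"] = ["HSG"] * 24 + ["LSG"] * 24
    df["subject_id"] = [f"s{i:02d}" for i in range(48)]
    return df
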