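import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import omicsgat as og

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

logging.getLogger("omicsgat").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_spec():
    return og.SyntheticSpec(
        n_samples=150, seed=7, effect_size=3.0,
        feature_counts={"EXP": 60, "MET": 40, "MUT": 30},
        omics_codes=("EXP", "MET", "MUT", "CLI"))


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    matrices, labels, clinical = og.generate_multiomics_cohort(tiny_spec)
    return matrices, labels, clinical


@pytest.fixture(scope="session")
def tiny_graph(tiny_cohort):
    matrices, _, _ = tiny_cohort
    return og.build_topk_graph(og.pearson_similarity(matrices[0]), k=3)
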