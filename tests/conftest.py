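import warnings

import numpy as np
import pytest

from wlsig.predict import RunFeatureExtractor, make_resamples
from wlsig.synthdata import SynthConfig, generate_annotation, generate_cohort

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(
        n_samples=60, n_genes=400, n_centers=3,
        planted_modules=[("lipid", 15, 1.2), ("virus", 10, 1.2)],
        module_overlap_fraction=0.4, clinical_n_factors=8, seed=2024)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return generate_annotation(small_config)


@pytest.fixture(scope="session")
def small_plan(small_cohort):
    return make_resamples(small_cohort.counts.sample_ids, n_runs=6,
                          train_fraction=0.8, seed=7)


@pytest.fixture(scope="session")
def small_extractor(small_cohort, small_plan):
    return RunFeatureExtractor(small_cohort, small_plan)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
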