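import warnings

import numpy as np
import pandas as pd
import pytest

from tfaflow import syndata
from tfaflow.preprocess import preprocess_pipeline
from tfaflow.repertoire import ModuleRepertoire


@pytest.fixture(scope="session")
def small_config():
    return syndata.SimConfig(n_patients=10, frac_gvhd=0.7, followup_days=150,
                             seed=11)


@pytest.fixture(scope="session")
def cohort(small_config):
    return syndata.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def processed(cohort):
    """Preprocessed expression + aligned annotations for the small cohort."""
    hk = cohort.repertoire.loc[cohort.repertoire.module_id == "HK", "gene"].tolist()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr, report = preprocess_pipeline(cohort.ct, cohort.annotations, hk)
    ann = cohort.annotations[
        cohort.annotations.sample_id.isin(expr.log2.index)].reset_index(drop=True)
    return expr, ann, report


@pytest.fixture(scope="session")
def repertoire_obj(cohort):
    return ModuleRepertoire(cohort.repertoire)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
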