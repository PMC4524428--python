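import numpy as np
import pandas as pd
import pytest

from methrisk import globalmeth as gm
from methrisk import synthdata as sd


@pytest.fixture(scope="session")
def annotation():
    return sd.generate_annotation(500, seed=11)


@pytest.fixture(scope="session")
def small_study(annotation):
    """A 60-pair matched study with batch effects and a real injected effect."""
    cfg = sd.SimConfig(n_pairs=60, n_probes=500, seed=7, missing_rate=0.0)
    beta, sheet = sd.generate_pairs(cfg, annotation)
    return beta, sheet


@pytest.fixture(scope="session")
def null_study(annotation):
    """A 60-pair study with no case-control effect of any kind."""
    cfg = sd.SimConfig(n_pairs=60, n_probes=500, seed=13, missing_rate=0.0, effect_logor_per_sd=0.0)
    beta, sheet = sd.generate_pairs(cfg, annotation)
    return beta, sheet


@pytest.fixture()
def exposure(small_study):
    beta, sheet = small_study
    means = gm.sample_mean_methylation(beta)
    return (means - means.mean()) / means.std(ddof=1), sheet
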