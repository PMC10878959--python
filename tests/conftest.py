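import numpy as np
import pandas as pd
import pytest

from miredit.synthetic import (
    CohortSimConfig,
    PlantedEffect,
    simulate_feature_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-class, three-batch cohort with three planted features."""
    cfg = CohortSimConfig(
        n_per_class=60,
        n_batches=3,
        n_aom=40,
        n_aem=25,
        n_el=25,
        planted_effects=(
            PlantedEffect("syn-miR-0003-5p", "AOM", 2.0),
            PlantedEffect("syn-mir-0004_25g", "AEM", 2.0),
            PlantedEffect("syn-mir-0002_25_A_g", "EL", 0.35),
        ),
        seed=11,
    )
    aom, aem, el, meta, truth = simulate_feature_cohort(cfg)
    return {"cfg": cfg, "aom": aom, "aem": aem, "el": el, "meta": meta, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_refs():
    """Two tiny pre-miRNA references with known sequences."""
    return {
        "mirA": "ACGUACGUACGUACGUACGUAC",  # 22 nt
        "mirB": "GGGGCCCCAAAAUUUUGGGGCC",  # 22 nt
    }
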