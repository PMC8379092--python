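import numpy as np
import pytest

from diffperf.schema import Cohort, SubjectRecord
from diffperf.synthetic import (
    PlantedAssociation,
    PlantedEffect,
    SyntheticConfig,
    generate_cohort,
)

import pandas as pd


def small_config(seed: int = 0, effect_d: float = 1.0) -> SyntheticConfig:
    """A fast 40+24-subject cohort over 42 features with 3 planted
    effects and one planted association; used by stage-level tests."""
    effects = (
        PlantedEffect("perfusion__CBF__Precentral_R", 55.6, 49.2,
                      abs(55.6 - 49.2) / effect_d),
        PlantedEffect("diffusion__FA__genu_of_corpus_callosum", 0.346, 0.316,
                      abs(0.346 - 0.316) / effect_d),
        PlantedEffect("diffusion__MD__body_of_corpus_callosum", 7.8, 8.3,
                      abs(7.8 - 8.3) / effect_d),
    )
    assocs = (
        PlantedAssociation("diffusion__FA__genu_of_corpus_callosum",
                           "TMT_B", -0.45),
    )
    return SyntheticConfig(
        n_case=40,
        n_control=24,
        n_wm_labels=8,
        n_gm_labels=10,
        planted_effects=effects,
        planted_associations=assocs,
        seed=seed,
    )


@pytest.fixture
def small_cohort() -> Cohort:
    return generate_cohort(small_config(seed=7))


@pytest.fixture(scope="session")
def tiny_cohort() -> Cohort:
    """A deterministic 10-subject, 5-feature cohort built by hand."""
    rng = np.random.default_rng(42)
    subjects = [
        SubjectRecord(
            subject_id=f"T{i:02d}",
            diagnosis=int(i < 6),
            sex=int(i % 2),
            age=60.0 + i,
            education=9.0 + (i % 4),
            cognitive_scores={"MoCA": 20.0 + i, "TMT_B": 200.0 - 5 * i},
        )
        for i in range(10)
    ]
    cols = [
        "diffusion__FA__genu_of_corpus_callosum",
        "diffusion__MD__genu_of_corpus_callosum",
        "diffusion__AD__genu_of_corpus_callosum",
        "diffusion__RD__genu_of_corpus_callosum",
        "perfusion__CBF__Precentral_L",
    ]
    table = pd.DataFrame(
        rng.normal(size=(10, 5)),
        index=[s.subject_id for s in subjects],
        columns=cols,
    )
    return Cohort(subjects, table)
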