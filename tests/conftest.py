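import numpy as np
import pandas as pd
import pytest

from chronoval.synthetic import (
    CorpusSpec,
    DesignSpec,
    RatingGenParams,
    RTGenParams,
    default_vocabulary,
    generate_corpus,
    generate_ratings,
    generate_rt_experiment,
)


@pytest.fixture(scope="session")
def small_design() -> DesignSpec:
    """Within-subject four-block design, small enough for fast tests."""
    return DesignSpec.experiment2(n_subjects=8, items_per_category=3)


@pytest.fixture(scope="session")
def small_trials(small_design) -> pd.DataFrame:
    return generate_rt_experiment(small_design, RTGenParams(seed=42))


@pytest.fixture(scope="session")
def noiseless_params() -> RTGenParams:
    """Degenerate generator: every RT equals the deterministic cell mean."""
    return RTGenParams(
        match_effect=170.0,
        congruency_effect=0.0,
        domain_effect=0.0,
        practice_slope=0.0,
        subject_sd=0.0,
        item_sd=0.0,
        residual_sigma=0.0,
        error_base=0.0,
        error_mismatch_increment=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_ratings() -> pd.DataFrame:
    return generate_ratings(
        RatingGenParams(n_young=6, n_old=4, words_per_category=4, seed=7)
    )


@pytest.fixture(scope="session")
def small_corpus_spec() -> CorpusSpec:
    return CorpusSpec(
        n_documents=60,
        doc_length=30,
        vocabulary=default_vocabulary(words_per_category=5, n_fillers=10),
        association_strength=0.8,
        direction="both",
        seed=11,
    )


@pytest.fixture(scope="session")
def small_corpus(small_corpus_spec):
    return generate_corpus(small_corpus_spec)
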