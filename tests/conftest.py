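import warnings

import pytest

from helpchoice.qc import apply_decision_qc, apply_rating_qc, compute_consensus
from helpchoice.synth import EFA_QUESTIONS, SyntheticConfig, generate_all


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=3, n_scenarios=40, n_raters_per_scenario=10,
                           scenarios_per_rater=20, n_participants=24,
                           trials_per_participant=20, embedding_dim=8,
                           n_semantic_clusters=5)


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_all(small_config)


@pytest.fixture(scope="session")
def study_config():
    """Study-shaped conditions at reduced participant count."""
    return SyntheticConfig(seed=11, n_participants=60,
                           trials_per_participant=30)


@pytest.fixture(scope="session")
def study_data(study_config):
    return generate_all(study_config)


@pytest.fixture(scope="session")
def study_clean(study_data):
    dec, _ = apply_decision_qc(study_data["decisions"])
    rat, _ = apply_rating_qc(study_data["ratings"])
    return dec, rat


@pytest.fixture(scope="session")
def study_consensus(study_clean):
    dec, rat = study_clean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cons = compute_consensus(rat, decisions=dec)
    return cons.set_index("scenario_id")


@pytest.fixture(scope="session")
def efa_matrix(study_consensus):
    X = study_consensus[[f"{q}_mean" for q in EFA_QUESTIONS]].copy()
    X.columns = list(EFA_QUESTIONS)
    return X
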