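import logging

import pandas as pd
import pytest

from mcedscreen import (
    CsoStratifiedPositives,
    generate_synthetic_inputs,
    incidence_round_interception,
    stratify_positives,
    stratum_incidence,
)

logging.getLogger("mcedscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def truth():
    """Default realistic synthetic study conditions."""
    return generate_synthetic_inputs(seed=0)


@pytest.fixture(scope="session")
def truth_easy():
    return generate_synthetic_inputs(seed=0, difficulty="easy")


@pytest.fixture(scope="session")
def truth_adversarial():
    return generate_synthetic_inputs(seed=0, difficulty="adversarial")


@pytest.fixture(scope="session")
def reference_run(truth):
    """Analytic pipeline outputs on the reference stratum (65-69 female, any)."""
    return truth.run_reference_pipeline()


@pytest.fixture(scope="session")
def stratified(truth, reference_run):
    interception, strat, metrics, outcomes = reference_run
    return strat


def make_positives(tp_rows, fp, labels, clinical_cso):
    """Hand-built stratified-positives pool for closed-form checks.

    tp_rows: (cancer_class, stage_detected, stage_clinical, predicted_cso, count)
    """
    tp = pd.DataFrame(
        tp_rows,
        columns=["cancer_class", "stage_detected", "stage_clinical", "predicted_cso", "count"],
    )
    return CsoStratifiedPositives(
        tp=tp, fp=pd.Series(fp, index=labels, dtype=float), clinical_cso=clinical_cso
    )
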