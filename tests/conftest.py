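import numpy as np
import pandas as pd
import pytest

from slepd import simulate as sim
from slepd.nof1 import GeneSignature, SignatureCall


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully structured cohort: 30 patients/arm, 30 genes
    (20 in the IFN block), default elevation and PD effect."""
    expr, meta, truth = sim.simulate_expression(
        n_patients=30, n_genes=30, n_ifn_genes=20, seed=101
    )
    return expr, meta, truth


@pytest.fixture(scope="session")
def ifn_signature(small_sim):
    _, _, truth = small_sim
    genes = truth.baseline_elevation[truth.baseline_elevation > 0].index
    return GeneSignature(name="IFN_BLOCK", genes=frozenset(genes))


def calls_from_truth(truth):
    """SignatureCall list taken directly from the generator's truth,
    for tests that exercise the trajectory machinery in isolation."""
    return [
        SignatureCall(patient_id=pid, signature="TRUTH", status=status,
                      wilcoxon_p=0.0, median_delta=1.0 if status == "high" else -1.0)
        for pid, status in truth.patient_status.items()
    ]


@pytest.fixture
def truth_calls(small_sim):
    return calls_from_truth(small_sim[2])
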