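import numpy as np
import pandas as pd
import pytest

from snfsig.datatypes import ClusterAssignment
from snfsig.preprocess import preprocess_all
from snfsig.simulate import (
    SyntheticCohortConfig,
    default_genome,
    generate_cohort,
)
from snfsig.snf import SNFParams, fuse_omics


@pytest.fixture(scope="session")
def genome():
    return default_genome(seed=3)


@pytest.fixture(scope="session")
def cohort():
    """Planted 3-cluster cohort under the default study conditions."""
    cfg = SyntheticCohortConfig(n_patients=90, k_clusters=3, effect_size=2.0,
                                informative_fraction=0.1, missing_rate=0.05,
                                seed=11)
    matrices, truth, clinical = generate_cohort(cfg)
    return cfg, matrices, truth, clinical


@pytest.fixture(scope="session")
def processed_cohort(cohort):
    cfg, matrices, truth, clinical = cohort
    processed = preprocess_all(list(matrices.values()))
    return cfg, processed, truth, clinical


@pytest.fixture(scope="session")
def fused_network(processed_cohort):
    _, processed, _, _ = processed_cohort
    return fuse_omics(processed, SNFParams())


@pytest.fixture(scope="session")
def truth_assignment(processed_cohort, fused_network):
    _, _, truth, _ = processed_cohort
    return ClusterAssignment(patient_ids=fused_network.patient_ids,
                             labels=truth.labels, k=3)


def make_block_network(sizes, within=0.9, between=0.05, noise=0.0, seed=0):
    """Noisy block-diagonal similarity matrix with patient ids."""
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    w = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if noise:
        e = rng.normal(0, noise, (n, n))
        w = np.clip(w + (e + e.T) / 2, 1e-6, None)
    np.fill_diagonal(w, 1.0)
    ids = [f"P{i:03d}" for i in range(n)]
    from snfsig.datatypes import PatientSimilarityNetwork

    return PatientSimilarityNetwork(pd.DataFrame(w, index=ids, columns=ids)), labels + 1
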