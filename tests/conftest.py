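"""Shared fixtures: small planted-phenotype cohorts and trained models.

Session scope keeps the expensive artifacts (the desk-scale standard
cohort, its prototypes, trained models) shared between the unit and
acceptance tests.
"""

import numpy as np
import pytest

import protomil as pm


@pytest.fixture(scope="session")
def bank8():
    """K=4 well-separated phenotypes in d1=8 (recovery-friendly dimension)."""
    return pm.generate_phenotype_bank(K=4, d1=8, separation=8.0, scale=1.0, seed=0)


@pytest.fixture(scope="session")
def cohort8(bank8):
    """40-bag cohort in d1=8 used for clustering/recovery tests."""
    spec = pm.CohortSpec(n_bags=40, d1=8, seed=1)
    return pm.generate_cohort(spec, bank8)


@pytest.fixture(scope="session")
def protos8(cohort8):
    return pm.build_prototypes(cohort8.split_bags("train"))


@pytest.fixture(scope="session")
def std_bank():
    """Standard desk-scale bank: K=4, d1=64, separation 8."""
    return pm.generate_phenotype_bank(K=4, d1=64, separation=8.0, scale=1.0, seed=0)


@pytest.fixture(scope="session")
def std_cohort(std_bank):
    """Standard synthetic cohort: 200 bags, d1=64, tau=0.1, 40% positive."""
    return pm.generate_cohort(pm.CohortSpec(seed=0), std_bank)


@pytest.fixture(scope="session")
def std_protos(std_cohort):
    return pm.build_prototypes(std_cohort.split_bags("train"))


@pytest.fixture(scope="session")
def trained_std_states(std_cohort, std_protos):
    """Cluster-mode mean-head models trained on the standard cohort, 3 seeds."""
    states = []
    for s in range(3):
        mcfg = pm.ModelConfig(d1=64, prototype_mode="cluster", head="mean", seed=s)
        tcfg = pm.TrainConfig(seed=s, epochs=30)
        state, history = pm.train(std_cohort, std_protos, mcfg, tcfg)
        states.append((state, history))
    return states


@pytest.fixture
def toy_bag():
    rng = np.random.default_rng(7)
    feats = rng.standard_normal((5, 6))
    coords = np.array([[0, 0], [256, 0], [512, 0], [0, 256], [256, 256]])
    return pm.FeatureBag(bag_id="toy", features=feats, coords=coords, label=1)


@pytest.fixture
def tiny_protos():
    rng = np.random.default_rng(3)
    return pm.PrototypeSet(
        embeddings=rng.standard_normal((4, 6)),
        stage1_counts=[2, 3],
        bag_ids=["a", "b"],
    )
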