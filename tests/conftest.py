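import numpy as np
import pytest
import scipy.sparse as sp

import genotopics as gt


@pytest.fixture
def tiny_pm() -> gt.PhenotypeMatrix:
    """Hand-built 4x3 binary matrix with readable labels."""
    X = sp.csr_matrix(
        np.array(
            [[1, 0, 1],
             [1, 1, 0],
             [0, 1, 1],
             [1, 1, 1]], dtype=np.int8
        )
    )
    return gt.PhenotypeMatrix(
        X=X, individual_ids=["a", "b", "c", "d"], phecodes=["p1", "p2", "p3"]
    )


@pytest.fixture(scope="session")
def small_cohort() -> gt.SyntheticCohort:
    """A reduced planted cohort used by several structural tests."""
    cfg = gt.SimulationConfig(
        n_individuals=600, n_phecodes=120, n_topics=4, core_size=8, seed=42
    )
    return gt.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort() -> gt.SyntheticCohort:
    """The default study conditions: n=3000, m=400, k=6, planted effect 0.8."""
    return gt.simulate_cohort(gt.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_model(default_cohort) -> gt.TopicModel:
    cfg = gt.NMFConfig(k=6, lam=0.2, gamma=0.5, seed=7, max_iter=300, tol=1e-5)
    return gt.fit_nmf(default_cohort.X, cfg)


def truth_descriptors(cohort: gt.SyntheticCohort) -> gt.TopicDescriptors:
    """Planted cores as a descriptor object for agreement scoring."""
    sets = cohort.core_phecodes
    return gt.TopicDescriptors(
        topics=[sorted(s) for s in sets],
        weights=[np.ones(len(s)) for s in sets],
        t=cohort.config.core_size,
    )
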