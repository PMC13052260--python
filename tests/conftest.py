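import dataclasses

import numpy as np
import pytest

import cytoscore as cs


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale two-group cohort with planted effects (8 clusters)."""
    cfg = cs.make_default_config(
        seed=11, n_clusters=8, samples_per_group=5, events_per_sample=600
    )
    matrices, meta, truth = cs.generate_cohort(cfg)
    return cfg, matrices, meta, truth


@pytest.fixture(scope="session")
def blob_data():
    """Three well-separated Gaussian blobs with known labels."""
    rng = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0], [0.0, 8.0, 0.0]])
    X = np.vstack([rng.normal(c, 1.0, size=(500, 3)) for c in centers])
    y = np.repeat([0, 1, 2], 500)
    return X, y


@pytest.fixture(scope="session")
def two_cohort_fixture():
    """Paired cohorts sharing cluster structure on the shared panel."""
    cfg1 = cs.make_default_config(
        seed=23, n_clusters=6, samples_per_group=4, events_per_sample=700
    )
    m1, meta1, t1 = cs.generate_cohort(cfg1)
    idx = [cfg1.panel_full.index(m) for m in cfg1.panel_shared]
    cfg4 = cs.make_default_config(
        seed=23, n_clusters=6, samples_per_group=3, events_per_sample=700,
        cohort="Cohort4", panel=cfg1.panel_shared, shared=cfg1.panel_shared,
    )
    cfg4 = dataclasses.replace(
        cfg4,
        cluster_means=cfg1.cluster_means[:, idx],
        cluster_sds=cfg1.cluster_sds[:, idx],
    )
    m4, meta4, t4 = cs.generate_cohort(cfg4)
    return cfg1, m1, meta1, t1, cfg4, m4, meta4, t4
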