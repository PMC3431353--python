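"""Shared ensembles for the analysis-pipeline tests.

The simulated ensembles are deliberately modest (about a quarter of the
sizes used for the headline numbers) so the whole suite stays fast; the
assertions that depend on them use correspondingly generous Monte-Carlo
margins.
"""

import pytest

from tugofwar import referential_set, simulate_ensemble
from tugofwar.segmentation import segment_trajectories


@pytest.fixture(scope="session")
def rs_config():
    return referential_set()


@pytest.fixture(scope="session")
def rs_ensemble(rs_config):
    # 1000 trajectories: the third velocity mode is a marginal shoulder in
    # smaller ensembles and the four-Gaussian mode-structure checks need
    # it resolved
    return simulate_ensemble(rs_config, 1000, base_seed=1042)


@pytest.fixture(scope="session")
def rs_segments(rs_ensemble):
    return segment_trajectories(rs_ensemble)


@pytest.fixture(scope="session")
def k03_ensemble(rs_config):
    return simulate_ensemble(rs_config.with_stiffness(0.3), 100, base_seed=1077)


@pytest.fixture(scope="session")
def k03_segments(k03_ensemble):
    return segment_trajectories(k03_ensemble)


@pytest.fixture(scope="session")
def set1_segments():
    from tugofwar import dispersion_set
    return segment_trajectories(simulate_ensemble(dispersion_set(), 150,
                                                  base_seed=2101))


@pytest.fixture(scope="session")
def set2_segments():
    from tugofwar import aggregation_set
    return segment_trajectories(simulate_ensemble(aggregation_set(), 150,
                                                  base_seed=2102))


@pytest.fixture(scope="session")
def imbalanced_segments(rs_config):
    """Referential set with one extra backward motor (2 vs 3)."""
    from dataclasses import replace
    cfg = rs_config.replace(
        backward=replace(rs_config.backward, count=3))
    return segment_trajectories(simulate_ensemble(cfg, 80, base_seed=2103))
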