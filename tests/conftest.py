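import numpy as np
import pytest

import boldcausal as bc


@pytest.fixture(scope="session")
def study_panel():
    """Study-shaped panel: 20 subjects x 2 conditions x 2 blocks x 100 volumes,
    9 ROIs at TR = 1.6 s, with condition-specific graphs and confounds."""
    graphs = bc.default_study_graphs(3)
    subjects = bc.study_subjects(20)
    for s in subjects:
        s.condition_graph_overrides = graphs
    panel, confounds = bc.simulate_panel(graphs["resting"], subjects, seed=3)
    return panel, confounds


@pytest.fixture(scope="session")
def small_panel():
    """Small panel for fast preprocessing tests: 3 subjects, 2 x 2 x 60."""
    graphs = bc.default_study_graphs(5)
    subjects = bc.study_subjects(3, block_length=60)
    for s in subjects:
        s.condition_graph_overrides = graphs
    return bc.simulate_panel(graphs["resting"], subjects, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
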