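import numpy as np
import pandas as pd
import pytest

from tgxddi.classify import DDI, NON_DDI, LabeledProfileSet
from tgxddi.panel import make_panel
from tgxddi.simulate import (
    EffectModel,
    SimDesign,
    default_viability_curves,
    ring_trial_design,
    simulate_experiment,
    simulate_training_set,
)


@pytest.fixture(scope="session")
def panel():
    return make_panel(n_housekeeping=10, seed=1)


@pytest.fixture(scope="session")
def effect():
    return EffectModel()


@pytest.fixture(scope="session")
def training(panel, effect):
    return simulate_training_set(panel, effect, n_ddi=14, n_nonddi=14, seed=7)


@pytest.fixture(scope="session")
def small_design():
    """A reduced two-lab design for fast IO / pipeline-stage tests."""
    full = ring_trial_design(n_labs=2, seed=5)
    return SimDesign(
        labs=full.labs,
        compounds=full.compounds[:4],
        controls=full.controls,
        n_replicates=3,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_experiment(small_design, panel, effect):
    curves = default_viability_curves(small_design)
    return simulate_experiment(small_design, panel, effect, curves)


@pytest.fixture(scope="session")
def toy_training():
    """Well-separated two-gene toy training set (2 agents per class)."""
    profiles = pd.DataFrame(
        {
            "d1": [9.0, 10.0],
            "d2": [11.0, 10.0],
            "n1": [-9.0, -10.0],
            "n2": [-11.0, -10.0],
        },
        index=["g1", "g2"],
    )
    labels = pd.Series({"d1": DDI, "d2": DDI, "n1": NON_DDI, "n2": NON_DDI})
    return LabeledProfileSet(profiles=profiles, labels=labels)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
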