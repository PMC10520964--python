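import numpy as np
import pandas as pd
import pytest

from tardistress.life_history import ClutchRecord, FemaleRecord


@pytest.fixture
def two_female_cohort():
    """Two hand-built females: one with two clutches, one barren."""
    f1 = FemaleRecord(
        female_id="A1",
        generation="F1",
        rearing_temperature_C=5,
        lifespan_days=120,
        n_molts=3,
        clutches=(
            ClutchRecord(1, 34, 3, 2, (22.0, 24.0)),
            ClutchRecord(2, 48, 4, 3, (20.0, 21.0, 23.0)),
        ),
    )
    f2 = FemaleRecord(
        female_id="A2",
        generation="F2",
        rearing_temperature_C=15,
        lifespan_days=60,
        n_molts=1,
        clutches=(),
    )
    return [f1, f2]


@pytest.fixture(scope="session")
def small_experiment():
    """A small planted-truth count experiment shared across tests."""
    from tardistress.simulate import ExpressionGenConfig, generate_expression_experiment

    cfg = ExpressionGenConfig(n_genes=400, frac_de=0.1, per_step_log2fc=1.0, seed=42)
    return generate_expression_experiment(cfg)
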