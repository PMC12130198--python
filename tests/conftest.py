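import numpy as np
import pytest

from gutflux.core import MetabolicModel, Metabolite, Reaction


@pytest.fixture
def chain_model() -> MetabolicModel:
    """EX_A (uptake <= 10) -> A -> B -> demand; every flux forced to the
    uptake bottleneck at optimum."""
    return MetabolicModel(
        id="chain",
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, -10.0, 1000.0),
            Reaction("R_AB", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("DM_B", {"B": -1.0}, 0.0, 1000.0),
        ],
        objective="DM_B",
    )


@pytest.fixture
def diamond_model() -> MetabolicModel:
    """Uptake of A; two parallel routes A->B; demand of B fixed to 10."""
    return MetabolicModel(
        id="diamond",
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, -10.0, 1000.0),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("R2", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("DM_B", {"B": -1.0}, 10.0, 10.0),
        ],
        objective="DM_B",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
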