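import numpy as np
import pytest

from partikin.fixtures import make_bimolecular_scenario
from partikin.model_io import (
    Geometry,
    Localisation,
    ReactionDef,
    RType,
    SpeciesDef,
    build_model,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def box3um():
    return Geometry(3e-6, 3e-6, 3e-6)


@pytest.fixture
def sol_sol_model():
    """A + B -> AB, both soluble, k_f = 1e6 M^-1 s^-1, 100 nM each."""
    model, _ = make_bimolecular_scenario()
    return model


@pytest.fixture
def reversible_model(box3um):
    """R + S <-> RS with a membrane receptor."""
    species = [
        SpeciesDef("R", Localisation.MEMBRANE, 3e-13, 1e-7, {"r": 1}),
        SpeciesDef("S", Localisation.SOLUBLE, 3e-11, 1e-7, {"s": 1}),
        SpeciesDef("RS", Localisation.MEMBRANE, 3e-13, 0.0, {"r": 1, "s": 1}),
    ]
    reactions = [
        ReactionDef(RType.REVERSIBLE, ("R", "S"), ("RS",), 1e6, 1e-3,
                    geometry_class="mem_sol"),
    ]
    return build_model(species, reactions, box3um, 0.05)
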