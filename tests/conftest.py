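import numpy as np
import pytest

from fluxshift.expression import DeregulationCall
from fluxshift.model import MetabolicModel, Metabolite, Reaction, apply_environment
from fluxshift.gpr import parse_gpr
from fluxshift.synthetic import ToySpec, default_environment, make_toy_model


def chain_model(uptake_ub: float = 10.0) -> MetabolicModel:
    """Linear chain EX_A -> transport -> conversion -> EX_B.

    Exchanges follow the convention that negative flux is uptake
    (EX_a: a_e <-> nothing, lb = -uptake_ub), so every internal reaction
    can carry between 0 and uptake_ub units of flux.
    """
    mets = [Metabolite("a_e", compartment="e"), Metabolite("a_c", compartment="c"),
            Metabolite("b_c", compartment="c"), Metabolite("b_e", compartment="e")]
    rxns = [
        Reaction("EX_a", {"a_e": -1.0}, -uptake_ub, 0.0),
        Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}, 0.0, 1000.0, gpr=parse_gpr("gT")),
        Reaction("CONV", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0, gpr=parse_gpr("gC1 and gC2")),
        Reaction("T_b", {"b_c": -1.0, "b_e": 1.0}, 0.0, 1000.0, gpr=parse_gpr("gB1 or gB2")),
        Reaction("EX_b", {"b_e": -1.0}, 0.0, 1000.0),
    ]
    return MetabolicModel("chain", mets, rxns, biomass_reaction_id="T_b")


@pytest.fixture(scope="session")
def chain():
    return chain_model()


@pytest.fixture(scope="session")
def toy_model():
    """Environment-applied toy network used across modules."""
    return apply_environment(make_toy_model(ToySpec(seed=7)), default_environment())


def up(ratio: float) -> DeregulationCall:
    return DeregulationCall("up", ratio)


def down(ratio: float) -> DeregulationCall:
    return DeregulationCall("down", ratio)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
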