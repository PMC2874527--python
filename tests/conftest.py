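import logging

import numpy as np
import pytest

import linlogccm as ll


@pytest.fixture(autouse=True)
def _quiet_clamp_warnings(caplog):
    logging.getLogger("linlogccm.linlog").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def hepg2():
    return ll.load_packaged_model()


@pytest.fixture(scope="session")
def hepg2_truth(hepg2):
    """Seeded stable synthetic parameterization of the packaged network."""
    J0 = ll.sample_reference_flux(hepg2, seed=1)
    return ll.sample_parameters(hepg2, J0, seed=1)


@pytest.fixture(scope="session")
def toy():
    model, truth = ll.toy_truth(seed=3, noise_cv=0.05)
    return model, truth


def two_species_chain():
    """Boundary-fed A -> B chain without extracellular pools (no drift)."""
    species = [
        ll.Species(id="A_in"), ll.Species(id="B_in"),
        ll.Species(id="S_nb", compartment="boundary", balanced=False),
        ll.Species(id="P_nb", compartment="boundary", balanced=False),
    ]
    reactions = [
        ll.Reaction(id="b1", stoichiometry={"S_nb": -1, "A_in": 1}),
        ll.Reaction(id="b2", stoichiometry={"A_in": -1, "B_in": 1}),
        ll.Reaction(id="b3", stoichiometry={"B_in": -1, "P_nb": 1}),
    ]
    return ll.NetworkModel(species=species, reactions=reactions, name="chain2")


def chain2_param(eps=None, c0=None, J0val=1.0):
    model = two_species_chain()
    values = eps or {("b1", "A_in"): -0.4,
                     ("b2", "A_in"): 0.8, ("b2", "B_in"): -0.3,
                     ("b3", "B_in"): 0.9}
    ref = ll.ReferenceState(
        J0={"b1": J0val, "b2": J0val, "b3": J0val},
        c0=c0 or {"A_in": 1.5, "B_in": 0.5})
    p = ll.Parameterization(
        elasticities=ll.ElasticityMatrix(
            pattern=ll.elasticity_pattern(model), values=values),
        reference=ref)
    return model, p


@pytest.fixture
def chain2():
    return chain2_param()


def supply_demand_model():
    """One balanced species X with a supply and a demand reaction."""
    species = [
        ll.Species(id="X_in"),
        ll.Species(id="S_nb", compartment="boundary", balanced=False),
        ll.Species(id="P_nb", compartment="boundary", balanced=False),
    ]
    reactions = [
        ll.Reaction(id="supply", stoichiometry={"S_nb": -1, "X_in": 1}),
        ll.Reaction(id="demand", stoichiometry={"X_in": -1, "P_nb": 1}),
    ]
    return ll.NetworkModel(species=species, reactions=reactions, name="sd")


def supply_demand_param(eps_supply, eps_demand, J0=1.0, c0=1.0):
    model = supply_demand_model()
    values = {}
    if eps_supply is not None:
        values[("supply", "X_in")] = eps_supply
    if eps_demand is not None:
        values[("demand", "X_in")] = eps_demand
    p = ll.Parameterization(
        elasticities=ll.ElasticityMatrix(
            pattern=ll.elasticity_pattern(model), values=values),
        reference=ll.ReferenceState(J0={"supply": J0, "demand": J0},
                                    c0={"X_in": c0}))
    return model, p


def oscillator_model():
    """Two decoupled pools with antisymmetric cross-regulation: the dynamic
    matrix is [[-1, 2], [-2, -1]] giving one damped conjugate pair."""
    species = [
        ll.Species(id="A_in"), ll.Species(id="B_in"),
        ll.Species(id="S_nb", compartment="boundary", balanced=False),
        ll.Species(id="T_nb", compartment="boundary", balanced=False),
        ll.Species(id="P_nb", compartment="boundary", balanced=False),
        ll.Species(id="Q_nb", compartment="boundary", balanced=False),
    ]
    reactions = [
        ll.Reaction(id="ia", stoichiometry={"S_nb": -1, "A_in": 1}),
        ll.Reaction(id="ib", stoichiometry={"T_nb": -1, "B_in": 1}),
        ll.Reaction(id="oa", stoichiometry={"A_in": -1, "P_nb": 1},
                    inhibitors=["B_in"]),
        ll.Reaction(id="ob", stoichiometry={"B_in": -1, "Q_nb": 1},
                    activators=["A_in"]),
    ]
    model = ll.NetworkModel(species=species, reactions=reactions, name="osc")
    values = {("oa", "A_in"): 1.0, ("oa", "B_in"): -2.0,
              ("ob", "B_in"): 1.0, ("ob", "A_in"): 2.0}
    p = ll.Parameterization(
        elasticities=ll.ElasticityMatrix(
            pattern=ll.elasticity_pattern(model), values=values),
        reference=ll.ReferenceState(
            J0={"ia": 1.0, "ib": 1.0, "oa": 1.0, "ob": 1.0},
            c0={"A_in": 1.0, "B_in": 1.0}))
    return model, p


def c_hat_vector(model, mapping=None):
    vec = np.ones(len(model.balanced_ids))
    for sid, v in (mapping or {}).items():
        vec[model.balanced_ids.index(sid)] = v
    return vec
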