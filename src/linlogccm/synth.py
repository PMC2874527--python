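"""Ground-truth sampling and synthetic stimulus-response datasets.

Emulates the glucose-deprivation experiment: a stable linlog truth is drawn
around a sampled reference state, the perturbed system is simulated on the
experimental time grid, and multiplicative noise with per-species CV yields
triplicate records plus a pre-stimulus reference block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from . import mca
from .estimation import MeasurementSet
from .linlog import (DEFAULT_TIME_GRID, ElasticityMatrix, LinlogSystem,
                     Parameterization, PerturbationDesign, ReferenceState,
                     elasticity_pattern, initial_state)
from .network import NetworkModel, Reaction, Species, stoichiometric_matrix

#: default observed set of the packaged model: 5 extracellular + 20
#: intracellular metabolites quantified in the stimulus-response experiment
DEFAULT_OBSERVED = (
    "GLC_ex", "LAC_ex", "PYR_ex", "ALA_ex", "SER_ex",
    "GLC_in", "PEP_in", "G3P_in", "DHAP_in", "F16P_in", "G6P_in", "6PG_in",
    "S7P_in", "RIBO5P_in", "RIBU5P_in", "FUM_in", "MAL_in", "CISAC_in",
    "ISOCIT_in", "CIT_in", "LAC_in", "PYR_in", "ATP_in", "NAD_in", "NADP_in",
)


@dataclass
class SyntheticTruth:
    parameterization: Parameterization
    design: PerturbationDesign
    noise_cv: float = 0.15
    seed: int = 0


def sample_reference_flux(model: NetworkModel, seed: int = 0,
                          split: float = 0.57,
                          split_reactions: tuple[str, str] = ("r2", "r10"),
                          bounds: tuple[float, float] = (0.05, 10.0)
                          ) -> dict[str, float]:
    """Sample a strictly positive intracellular steady-state flux vector.

    Solves a linear program with a seeded random objective over the null
    space of the intracellular stoichiometric matrix, all fluxes positive in
    the reference direction.  When both *split_reactions* are present, the
    branch split a/(a+b) is pinned to *split* (the glycolysis:PPP ratio at
    the G6P node defaults to 57:43).
    """
    rng = np.random.default_rng(seed)
    system = stoichiometric_matrix(model)
    rows = [system.row(s) for s in model.intracellular_ids]
    N_int = system.N[rows, :]
    n = len(model.reaction_ids)
    A_eq = [N_int]
    b_eq = [np.zeros(N_int.shape[0])]
    ridx = {r: i for i, r in enumerate(model.reaction_ids)}
    ra, rb = split_reactions
    if ra in ridx and rb in ridx:
        row = np.zeros(n)
        row[ridx[ra]] = 1.0 - split
        row[ridx[rb]] = -split
        A_eq.append(row[None, :])
        b_eq.append(np.zeros(1))
    # random convex combination of LP vertices: feasible (the constraint set
    # is convex) and varies continuously with the seed
    vertices = []
    for _ in range(3):
        res = linprog(rng.uniform(0.1, 1.0, n) * rng.choice([-1.0, 1.0], n),
                      A_eq=np.vstack(A_eq), b_eq=np.concatenate(b_eq),
                      bounds=[bounds] * n, method="highs")
        if res.status != 0:
            resid = N_int @ np.full(n, bounds[0])
            bad = [model.intracellular_ids[i]
                   for i in np.nonzero(np.abs(resid) > 0)[0]]
            raise ValueError(
                "no strictly positive steady-state flux vector satisfies the "
                f"constraints (infeasible balances touch: "
                f"{', '.join(bad[:10])})")
        vertices.append(res.x)
    w = rng.dirichlet(np.ones(len(vertices)))
    J = np.einsum("i,ij->j", w, np.array(vertices))
    return dict(zip(model.reaction_ids, J))


def sample_parameters(model: NetworkModel, J0: dict[str, float],
                      seed: int = 0,
                      substrate_range: tuple[float, float] = (0.2, 1.2),
                      modifier_range: tuple[float, float] = (0.05, 0.4),
                      c0_log10_range: tuple[float, float] = (-0.3, 0.3),
                      ex_c0_log10_range: tuple[float, float] = (0.5, 1.5),
                      max_attempts: int = 1000) -> Parameterization:
    """Draw a stable parameterization with conventional elasticity signs.

    Substrates get positive, products negative elasticities; activators
    positive, inhibitors negative.  Candidates are rejected until both the
    dynamic Jacobian of the full reduced system and the intracellular
    control matrix are acceptable.
    """
    rng = np.random.default_rng(seed)
    pattern = elasticity_pattern(model)
    balanced = set(model.balanced_ids)
    extracellular = set(model.extracellular_ids)
    for _ in range(max_attempts):
        c0 = {s: float(10 ** rng.uniform(
                  *(ex_c0_log10_range if s in extracellular
                    else c0_log10_range)))
              for s in model.balanced_ids}
        values: dict[tuple[str, str], float] = {}
        for r in model.reactions:
            subs = [s for s in r.substrates if s in balanced]
            prods = [s for s in r.products if s in balanced]
            for s in subs:
                values[(r.id, s)] = float(rng.uniform(*substrate_range))
            for s in prods:
                values[(r.id, s)] = -float(rng.uniform(*substrate_range))
            for s in r.activators:
                if s in balanced and (r.id, s) not in values:
                    values[(r.id, s)] = float(rng.uniform(*modifier_range))
            for s in r.inhibitors:
                if s in balanced and (r.id, s) not in values:
                    values[(r.id, s)] = -float(rng.uniform(*modifier_range))
        param = Parameterization(
            elasticities=ElasticityMatrix(pattern=pattern, values=values),
            reference=ReferenceState(J0=dict(J0), c0=c0))
        jac = mca.jacobian(model, param)
        if not jac.stable:
            continue
        try:
            mca.control_coefficients(model, param)
        except np.linalg.LinAlgError:
            continue
        return param
    raise RuntimeError(
        f"no stable parameterization found in {max_attempts} attempts; "
        "try narrower elasticity magnitude ranges")


def glucose_deprivation_design(model: NetworkModel,
                               ref: ReferenceState,
                               observed=DEFAULT_OBSERVED,
                               replicates: int = 3) -> PerturbationDesign:
    """The paper-style perturbation: glucose removed, other medium pools
    reset to a fraction of their reference levels by the medium exchange."""
    post = {}
    for sid in model.extracellular_ids:
        if sid == "GLC_ex":
            post[sid] = 0.0
        else:
            # fresh medium carries little of the secreted/consumed pools
            post[sid] = 0.25 * ref.c0[sid]
    obs = [s for s in observed if s in model.balanced_ids]
    return PerturbationDesign(post_perturbation_extracellular=post,
                              time_grid=(0.0,) + DEFAULT_TIME_GRID[1:],
                              observed=obs, replicates=replicates)


def generate_dataset(model: NetworkModel, truth: SyntheticTruth,
                     sim_rtol: float = 1e-8) -> MeasurementSet:
    """Simulate the perturbed system and emit noisy replicate measurements.

    Noise is multiplicative Gaussian (truncated at a small positive floor)
    with coefficient of variation ``truth.noise_cv``; the pre-stimulus
    reference block is a noisy all-ones sample of the same design.
    """
    rng = np.random.default_rng(truth.seed)
    p = truth.parameterization
    design = truth.design
    sys_ = LinlogSystem(model, p)
    init = initial_state(model, design, p.reference)
    traj = sys_.simulate(init, design.time_grid, rtol=sim_rtol,
                         atol=sim_rtol * 1e-2)
    cv = truth.noise_cv
    comp = {s.id: s.compartment for s in model.species}
    records = []
    for sid in design.observed:
        col = traj.species_ids.index(sid)
        for i, t in enumerate(traj.times):
            true_val = traj.values[i, col]
            reps = true_val * (1.0 + cv * rng.standard_normal(
                design.replicates))
            reps = np.maximum(reps, 1e-9)
            if cv == 0:
                reps = np.full(design.replicates, true_val)
            sd = float(np.std(reps, ddof=1)) if design.replicates > 1 else 0.0
            for k in range(design.replicates):
                records.append((float(t), sid, comp[sid], k + 1,
                                float(reps[k]), sd))
    data = pd.DataFrame(records, columns=MeasurementSet.COLUMNS)
    # pre-stimulus (0-) sample: concentration estimates of the reference
    # levels, in the model's concentration units
    ref_records = []
    for sid in design.observed:
        c0_true = p.reference.c0[sid]
        reps = c0_true * (1.0 + cv * rng.standard_normal(design.replicates))
        reps = np.maximum(reps, 1e-9)
        if cv == 0:
            reps = np.full(design.replicates, c0_true)
        ref_records.append(
            (sid, comp[sid], float(np.mean(reps)),
             float(np.std(reps, ddof=1)) if design.replicates > 1 else 0.0))
    reference_block = pd.DataFrame(
        ref_records,
        columns=["species_id", "compartment", "c0_estimate", "c0_sd"])
    return MeasurementSet(records=data, reference_block=reference_block)


def make_truth(model: NetworkModel, seed: int = 0, noise_cv: float = 0.15,
               observed=DEFAULT_OBSERVED,
               flux_kwargs: dict | None = None,
               param_kwargs: dict | None = None) -> SyntheticTruth:
    """Convenience: flux + parameter sampling + deprivation design."""
    J0 = sample_reference_flux(model, seed=seed, **(flux_kwargs or {}))
    param = sample_parameters(model, J0, seed=seed, **(param_kwargs or {}))
    design = glucose_deprivation_design(model, param.reference,
                                        observed=observed)
    return SyntheticTruth(parameterization=param, design=design,
                          noise_cv=noise_cv, seed=seed)


# ---------------------------------------------------------------------------
# toy fixture: 6-reaction branched chain with one inhibitor loop
# ---------------------------------------------------------------------------

def toy_chain_model() -> NetworkModel:
    """Small fully observable network used for recovery benchmarks.

    X_ex --t1--> A --t2--> B --t3--> C --t4--> (sink), with drains
    A --t5--> and B --t6--> (sinks); C feedback-inhibits t2.
    """
    species = [
        Species(id="X_ex", name="substrate (medium)",
                compartment="extracellular", measured=True),
        Species(id="A_in", name="A", measured=True),
        Species(id="B_in", name="B", measured=True),
        Species(id="C_in", name="C", measured=True),
        Species(id="SINK1_nb", compartment="boundary", balanced=False),
        Species(id="SINK2_nb", compartment="boundary", balanced=False),
        Species(id="SINK3_nb", compartment="boundary", balanced=False),
    ]
    reactions = [
        Reaction(id="t1", name="uptake",
                 stoichiometry={"X_ex": -1, "A_in": 1}),
        Reaction(id="t2", name="conversion A->B",
                 stoichiometry={"A_in": -1, "B_in": 1},
                 inhibitors=["C_in"]),
        Reaction(id="t3", name="conversion B->C",
                 stoichiometry={"B_in": -1, "C_in": 1}),
        Reaction(id="t4", name="drain C",
                 stoichiometry={"C_in": -1, "SINK1_nb": 1}),
        Reaction(id="t5", name="drain A",
                 stoichiometry={"A_in": -1, "SINK2_nb": 1}),
        Reaction(id="t6", name="drain B",
                 stoichiometry={"B_in": -1, "SINK3_nb": 1}),
    ]
    return NetworkModel(species=species, reactions=reactions,
                        name="toy_chain")


# fluxes sized so relaxation times (~c0/J0) spread across the sampling grid
TOY_J0 = {"t1": 0.05, "t2": 0.035, "t3": 0.02, "t4": 0.02,
          "t5": 0.015, "t6": 0.015}


def toy_truth(seed: int = 0, noise_cv: float = 0.05,
              x_post: float = 0.2) -> tuple[NetworkModel, SyntheticTruth]:
    """Stable toy ground truth plus its perturbation design."""
    model = toy_chain_model()
    # unit reference concentrations: the normalized pre-stimulus block then
    # pins measured c0 at the truth, so recovery scores isolate elasticities
    param = sample_parameters(
        model, TOY_J0, seed=seed,
        substrate_range=(0.4, 1.5), modifier_range=(0.3, 1.0),
        c0_log10_range=(0.0, 0.0), ex_c0_log10_range=(0.69897, 0.69897))
    design = PerturbationDesign(
        post_perturbation_extracellular={
            "X_ex": x_post * param.reference.c0["X_ex"]},
        time_grid=DEFAULT_TIME_GRID,
        observed=["X_ex", "A_in", "B_in", "C_in"])
    return model, SyntheticTruth(parameterization=param, design=design,
                                 noise_cv=noise_cv, seed=seed)
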