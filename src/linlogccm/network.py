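"""Network representation, structural validation and stoichiometric reduction.

The model is a plain species/reactions description loaded from a JSON file.
Balanced species receive mass-balance rows in the stoichiometric matrix ``N``;
boundary species (clamped pools such as water, CO2 or the biomass drains) do
not.  Conserved moieties (left null vectors of ``N``) are detected over exact
rational arithmetic and used to build the reduced system (``N_R``, link matrix
``L``) with one dependent species per moiety.

Extracellular species are balanced (their levels are dynamic state variables)
but are exchange pools of a batch culture: they legitimately appear on only
one side of the network and are therefore exempt from the dead-end demotion
applied to intracellular species.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from math import gcd
from pathlib import Path

import numpy as np
import sympy

logger = logging.getLogger(__name__)

COMPARTMENTS = ("intracellular", "extracellular", "boundary")


class SchemaError(ValueError):
    """Raised when a model file violates the model schema."""


@dataclass
class Species:
    id: str
    name: str = ""
    compartment: str = "intracellular"
    balanced: bool = True
    reference_concentration: float | None = None
    measured: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise SchemaError(
                f"species {self.id!r}: unknown compartment {self.compartment!r}")
        if self.compartment == "boundary" and self.balanced:
            raise SchemaError(f"boundary species {self.id!r} cannot be balanced")
        if (self.reference_concentration is not None
                and not self.reference_concentration > 0):
            raise SchemaError(
                f"species {self.id!r}: reference concentration must be > 0")


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, Fraction] = field(default_factory=dict)
    activators: list[str] = field(default_factory=list)
    inhibitors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        coeffs = {}
        for sid, c in self.stoichiometry.items():
            frac = Fraction(str(c)).limit_denominator(10**6)
            if frac == 0:
                raise SchemaError(
                    f"reaction {self.id!r}: zero coefficient for {sid!r}")
            coeffs[sid] = frac
        self.stoichiometry = coeffs

    @property
    def substrates(self) -> list[str]:
        return [s for s, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [s for s, c in self.stoichiometry.items() if c > 0]

    @property
    def modifiers(self) -> list[str]:
        return list(self.activators) + list(self.inhibitors)


@dataclass
class NetworkModel:
    species: list[Species]
    reactions: list[Reaction]
    name: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------
    @property
    def species_by_id(self) -> dict[str, Species]:
        return {s.id: s for s in self.species}

    @property
    def reactions_by_id(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    @property
    def balanced_ids(self) -> list[str]:
        return [s.id for s in self.species if s.balanced]

    @property
    def intracellular_ids(self) -> list[str]:
        return [s.id for s in self.species
                if s.balanced and s.compartment == "intracellular"]

    @property
    def extracellular_ids(self) -> list[str]:
        return [s.id for s in self.species
                if s.balanced and s.compartment == "extracellular"]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if not self.reactions:
            raise SchemaError("model contains no reactions")
        if not self.species:
            raise SchemaError("model contains no species")
        seen: set[str] = set()
        for s in self.species:
            if s.id in seen:
                raise SchemaError(f"duplicate species id {s.id!r}")
            seen.add(s.id)
        rseen: set[str] = set()
        known = self.species_by_id
        for r in self.reactions:
            if r.id in rseen:
                raise SchemaError(f"duplicate reaction id {r.id!r}")
            rseen.add(r.id)
            for sid in r.stoichiometry:
                if sid not in known:
                    raise SchemaError(
                        f"reaction {r.id!r}: unknown species id {sid!r}")
            for sid in r.modifiers:
                if sid not in known:
                    raise SchemaError(
                        f"reaction {r.id!r}: unknown modifier {sid!r}")

    def dead_ends(self) -> list[str]:
        """Intracellular balanced species appearing on only one side."""
        produced: set[str] = set()
        consumed: set[str] = set()
        for r in self.reactions:
            produced.update(r.products)
            consumed.update(r.substrates)
        out = []
        for sid in self.intracellular_ids:
            if not (sid in produced and sid in consumed):
                out.append(sid)
        return out

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": [
                {"id": s.id, "name": s.name, "compartment": s.compartment,
                 "balanced": s.balanced,
                 "reference_concentration": s.reference_concentration,
                 "measured": s.measured}
                for s in self.species],
            "reactions": [
                {"id": r.id, "name": r.name,
                 "stoichiometry": {
                     sid: (int(c) if c.denominator == 1 else float(c))
                     for sid, c in r.stoichiometry.items()},
                 "activators": list(r.activators),
                 "inhibitors": list(r.inhibitors)}
                for r in self.reactions],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "NetworkModel":
        try:
            species = [Species(**{k: v for k, v in s.items()})
                       for s in payload["species"]]
            reactions = [Reaction(**{k: v for k, v in r.items()
                                     if k != "ec_number"})
                         for r in payload["reactions"]]
        except TypeError as exc:  # unexpected keys
            raise SchemaError(str(exc)) from exc
        return cls(species=species, reactions=reactions,
                   name=payload.get("name", "model"))


def load_network(model_file: str | Path) -> NetworkModel:
    """Load and validate a network model file.

    Intracellular species declared balanced that are produced-only or
    consumed-only are demoted to boundary with a warning; extracellular
    exchange pools are exempt.
    """
    with open(model_file) as fh:
        payload = json.load(fh)
    model = NetworkModel.from_dict(payload)
    demote = model.dead_ends()
    if demote:
        for sid in demote:
            logger.warning(
                "species %s is a dead end (one-sided); demoting to boundary",
                sid)
        species = []
        for s in model.species:
            if s.id in demote:
                species.append(Species(
                    id=s.id, name=s.name, compartment="boundary",
                    balanced=False, measured=s.measured))
            else:
                species.append(s)
        model = NetworkModel(species=species, reactions=model.reactions,
                             name=model.name)
    return model


def packaged_model_path() -> Path:
    return Path(resources.files("linlogccm") / "data" / "hepg2_ccm.model.json")


def load_packaged_model() -> NetworkModel:
    return load_network(packaged_model_path())


# ---------------------------------------------------------------------------
# stoichiometric system
# ---------------------------------------------------------------------------

@dataclass
class StoichiometricSystem:
    """Stoichiometric matrix plus (optionally) its moiety-reduced form."""

    model: NetworkModel
    balanced_ids: list[str]
    reaction_ids: list[str]
    N: np.ndarray                       # balanced x reactions, float
    N_rational: sympy.Matrix            # same, exact
    moieties: list[dict[str, int]] | None = None
    independent_ids: list[str] | None = None
    dependent_ids: list[str] | None = None
    N_R: np.ndarray | None = None
    L: np.ndarray | None = None         # balanced x independent
    offsets: np.ndarray | None = None   # balanced vector (moiety totals part)
    totals: list[float] | None = None

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.N))

    def row(self, sid: str) -> int:
        return self.balanced_ids.index(sid)


def stoichiometric_matrix(model: NetworkModel) -> StoichiometricSystem:
    """Build ``N`` over balanced species (rows) and reactions (columns)."""
    balanced = model.balanced_ids
    ridx = {s: i for i, s in enumerate(balanced)}
    N = np.zeros((len(balanced), len(model.reactions)))
    Nr = sympy.zeros(len(balanced), len(model.reactions))
    for j, r in enumerate(model.reactions):
        for sid, c in r.stoichiometry.items():
            if sid in ridx:
                N[ridx[sid], j] = float(c)
                Nr[ridx[sid], j] = sympy.Rational(c.numerator, c.denominator)
    return StoichiometricSystem(model=model, balanced_ids=balanced,
                                reaction_ids=model.reaction_ids,
                                N=N, N_rational=Nr)


def conserved_moieties(system: StoichiometricSystem) -> list[dict[str, int]]:
    """Integer nonnegative basis of the left null space of ``N``.

    Vectors are returned as {species_id: coefficient} maps, canonically
    ordered by their smallest participating species id.  If a basis vector
    cannot be scaled to a nonnegative integer vector it is kept as returned
    by the rational solver, with a warning.
    """
    null = system.N_rational.T.nullspace()
    moieties: list[dict[str, int]] = []
    for vec in null:
        entries = [sympy.Rational(x) for x in vec]
        denominators = [e.q for e in entries if e != 0]
        scale = 1
        for d in denominators:
            scale = scale * d // gcd(scale, d)
        ints = [int(e * scale) for e in entries]
        common = 0
        for v in ints:
            common = gcd(common, abs(v))
        if common > 1:
            ints = [v // common for v in ints]
        nonzero = [v for v in ints if v != 0]
        if all(v < 0 for v in nonzero):
            ints = [-v for v in ints]
        elif not all(v > 0 for v in nonzero):
            logger.warning("moiety basis vector has mixed signs; "
                           "returning raw rational basis vector")
        moieties.append({system.balanced_ids[i]: v
                         for i, v in enumerate(ints) if v != 0})
    moieties.sort(key=lambda m: min(m))
    system.moieties = moieties
    return moieties


def _build_reduction(balanced_ids: list[str], N: np.ndarray,
                     moieties: list[dict[str, int]],
                     c0: dict[str, float] | None):
    """Common machinery for reducing a (sub)system by its moieties.

    The dependent species of each moiety is its last member in species-file
    order.  Returns (independent_ids, dependent_ids, N_R, L, offsets, totals);
    offsets/totals are None when no reference concentrations are given.
    """
    order = {s: i for i, s in enumerate(balanced_ids)}
    dependents = []
    for m in moieties:
        members = sorted(m, key=order.get)
        dependents.append(members[-1])
    independent = [s for s in balanced_ids if s not in dependents]
    n_all, n_ind = len(balanced_ids), len(independent)
    L = np.zeros((n_all, n_ind))
    col = {s: j for j, s in enumerate(independent)}
    for s in independent:
        L[order[s], col[s]] = 1.0
    offsets = np.zeros(n_all)
    totals: list[float] = []
    for m, dep in zip(moieties, dependents):
        g_dep = m[dep]
        for s, g in m.items():
            if s != dep:
                L[order[dep], col[s]] = -g / g_dep
        if c0 is not None:
            missing = [s for s in m if s not in c0 or c0[s] is None]
            if missing:
                raise ValueError(
                    "reference concentration required for moiety member(s): "
                    + ", ".join(missing))
            T = sum(g * c0[s] for s, g in m.items())
            totals.append(T)
            offsets[order[dep]] = T / g_dep
    ind_rows = [order[s] for s in independent]
    N_R = N[ind_rows, :]
    return (independent, dependents, N_R, L,
            offsets if c0 is not None else None,
            totals if c0 is not None else None)


def reduce_system(system: StoichiometricSystem,
                  c0: dict[str, float] | None = None) -> StoichiometricSystem:
    """Fill ``N_R``, ``L`` and moiety totals on *system* (in place).

    Without ``c0`` the link matrix is built but totals/offsets stay unset.
    """
    if system.moieties is None:
        conserved_moieties(system)
    (ind, dep, N_R, L, offsets, totals) = _build_reduction(
        system.balanced_ids, system.N, system.moieties, c0)
    system.independent_ids = ind
    system.dependent_ids = dep
    system.N_R = N_R
    system.L = L
    system.offsets = offsets
    system.totals = totals
    if len(ind) != system.rank:
        raise ValueError(
            f"reduction inconsistent: {len(ind)} independent species but "
            f"rank(N) = {system.rank}")
    return system


def reconstruct(system: StoichiometricSystem,
                c_independent: np.ndarray) -> np.ndarray:
    """Map independent concentrations to the full balanced vector."""
    if system.L is None or system.offsets is None:
        raise ValueError("system not reduced with reference concentrations")
    return system.L @ c_independent + system.offsets


def structural_report(model: NetworkModel) -> dict:
    """Structural counts and violation scan for a loaded model."""
    from .linlog import elasticity_pattern  # local import avoids cycle

    system = stoichiometric_matrix(model)
    moieties = conserved_moieties(system)
    transports = [r.id for r in model.reactions
                  if {model.species_by_id[s].compartment
                      for s in r.stoichiometry
                      if model.species_by_id[s].balanced} >=
                  {"intracellular", "extracellular"}
                  or {model.species_by_id[s].compartment
                      for s in r.stoichiometry} == {"extracellular"}]
    n_inh = sum(len(r.inhibitors) for r in model.reactions)
    n_act = sum(len(r.activators) for r in model.reactions)
    by_comp = {"intracellular": len(model.intracellular_ids),
               "extracellular": len(model.extracellular_ids)}
    return {
        "model": model.name,
        "reactions": len(model.reactions),
        "transport_steps": len(transports),
        "transport_ids": transports,
        "balanced_species": len(model.balanced_ids),
        "balanced_by_compartment": by_comp,
        "moieties": len(moieties),
        "moiety_members": [sorted(m) for m in moieties],
        "rank": system.rank,
        "independent_species": system.rank,
        "inhibitions": n_inh,
        "activations": n_act,
        "regulatory_effects": n_inh + n_act,
        "elasticity_pattern_size": len(elasticity_pattern(model)),
        "dead_ends": model.dead_ends(),
    }
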