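import json
from fractions import Fraction

import numpy as np
import pytest

import linlogccm as ll
from linlogccm.network import SchemaError, _build_reduction


class TestLoadNetwork:
    def test_packaged_counts(self, hepg2):
        assert len(hepg2.reactions) == 49
        assert len(hepg2.balanced_ids) == 45
        assert len(hepg2.intracellular_ids) == 40
        assert len(hepg2.extracellular_ids) == 5

    def test_zero_reactions_is_schema_error(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text(json.dumps(
            {"species": [{"id": "A"}], "reactions": []}))
        with pytest.raises(SchemaError):
            ll.load_network(path)

    def test_unknown_species_names_reaction(self, tmp_path):
        payload = {"species": [{"id": "A"}],
                   "reactions": [{"id": "r1",
                                  "stoichiometry": {"A": -1, "GHOST": 1}}]}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(SchemaError, match="r1"):
            ll.load_network(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        payload = {"species": [{"id": "A"}, {"id": "A"}],
                   "reactions": [{"id": "r1", "stoichiometry": {"A": -1}}]}
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(SchemaError, match="duplicate"):
            ll.load_network(path)

    def test_produced_only_species_demoted(self, tmp_path, caplog):
        # declare the nucleotide-synthesis product as balanced: it is made
        # by one reaction and never consumed, so it must come back boundary
        payload = json.loads(ll.packaged_model_path().read_text())
        for s in payload["species"]:
            if s["id"] == "PRPP_nb":
                s["compartment"] = "intracellular"
                s["balanced"] = True
        path = tmp_path / "prpp.json"
        path.write_text(json.dumps(payload))
        with caplog.at_level("WARNING", logger="linlogccm.network"):
            model = ll.load_network(path)
        sp = model.species_by_id["PRPP_nb"]
        assert not sp.balanced and sp.compartment == "boundary"
        assert any("PRPP_nb" in rec.message for rec in caplog.records)

    def test_round_trip(self, hepg2, tmp_path):
        path = tmp_path / "rt.json"
        path.write_text(json.dumps(hepg2.to_dict()))
        again = ll.load_network(path)
        assert again.to_dict() == hepg2.to_dict()


class TestStoichiometricMatrix:
    def test_packaged_shape(self, hepg2):
        system = ll.stoichiometric_matrix(hepg2)
        assert system.N.shape == (45, 49)

    def test_r22_column(self, hepg2):
        system = ll.stoichiometric_matrix(hepg2)
        col = system.N[:, system.reaction_ids.index("r22")]
        nz = {system.balanced_ids[i]: col[i] for i in np.nonzero(col)[0]}
        assert nz == {"NADPH_in": -1.0, "NADP_in": 1.0}

    def test_fractional_coefficients_exact(self, hepg2):
        r40 = hepg2.reactions_by_id["r40"]
        assert r40.stoichiometry["NAD_in"] == Fraction(-3, 5)
        r41 = hepg2.reactions_by_id["r41"]
        assert r41.stoichiometry["ATP_in"] == Fraction(5, 2)

    def test_toy_single_reaction(self):
        model = ll.NetworkModel(
            species=[ll.Species(id="A"), ll.Species(id="B")],
            reactions=[ll.Reaction(id="r1",
                                   stoichiometry={"A": -1, "B": 1})])
        system = ll.stoichiometric_matrix(model)
        assert system.N.tolist() == [[-1.0], [1.0]]


class TestConservedMoieties:
    def test_packaged_three_unit_moieties(self, hepg2):
        system = ll.stoichiometric_matrix(hepg2)
        moieties = ll.conserved_moieties(system)
        assert [sorted(m) for m in moieties] == [
            ["ADP_in", "AMP_in", "ATP_in"],
            ["NADH_in", "NAD_in"],
            ["NADPH_in", "NADP_in"],
        ]
        assert all(set(m.values()) == {1} for m in moieties)

    def test_left_null_exact(self, hepg2):
        system = ll.stoichiometric_matrix(hepg2)
        import sympy
        for m in ll.conserved_moieties(system):
            g = sympy.zeros(1, 45)
            for sid, coef in m.items():
                g[0, system.row(sid)] = coef
            resid = g * system.N_rational
            assert all(x == 0 for x in resid)

    def test_rank_plus_moieties(self, hepg2):
        system = ll.stoichiometric_matrix(hepg2)
        moieties = ll.conserved_moieties(system)
        assert system.rank == 42
        assert system.rank + len(moieties) == 45

    def test_closed_two_cycle(self):
        model = ll.NetworkModel(
            species=[ll.Species(id="A"), ll.Species(id="B")],
            reactions=[
                ll.Reaction(id="f", stoichiometry={"A": -1, "B": 1}),
                ll.Reaction(id="b", stoichiometry={"B": -1, "A": 1})])
        system = ll.stoichiometric_matrix(model)
        assert ll.conserved_moieties(system) == [{"A": 1, "B": 1}]

    def test_open_chain_no_moiety(self):
        model = ll.NetworkModel(
            species=[ll.Species(id="A"), ll.Species(id="B"),
                     ll.Species(id="S", compartment="boundary",
                                balanced=False),
                     ll.Species(id="P", compartment="boundary",
                                balanced=False)],
            reactions=[
                ll.Reaction(id="r1", stoichiometry={"S": -1, "A": 1}),
                ll.Reaction(id="r2", stoichiometry={"A": -1, "B": 1}),
                ll.Reaction(id="r3", stoichiometry={"B": -1, "P": 1})])
        system = ll.stoichiometric_matrix(model)
        assert ll.conserved_moieties(system) == []


class TestReduceSystem:
    def test_packaged_42_independents(self, hepg2):
        system = ll.stoichiometric_matrix(hepg2)
        c0 = {s: 1.0 for s in hepg2.balanced_ids}
        ll.reduce_system(system, c0)
        assert len(system.independent_ids) == 42
        assert system.dependent_ids == ["AMP_in", "NADH_in", "NADPH_in"]

    def test_reconstruction_identity_at_reference(self, hepg2):
        rng = np.random.default_rng(0)
        system = ll.stoichiometric_matrix(hepg2)
        c0 = {s: float(v) for s, v in zip(
            hepg2.balanced_ids, rng.uniform(0.2, 3.0, 45))}
        ll.reduce_system(system, c0)
        c_full = np.array([c0[s] for s in system.balanced_ids])
        c_ind = np.array([c0[s] for s in system.independent_ids])
        from linlogccm.network import reconstruct
        assert np.allclose(reconstruct(system, c_ind), c_full, rtol=1e-12)

    def test_random_perturbation_preserves_totals(self, hepg2):
        rng = np.random.default_rng(1)
        system = ll.stoichiometric_matrix(hepg2)
        c0 = {s: 1.0 for s in hepg2.balanced_ids}
        ll.reduce_system(system, c0)
        from linlogccm.network import reconstruct
        for _ in range(5):
            c_ind = rng.uniform(0.3, 2.0, 42)
            c_full = reconstruct(system, c_ind)
            for m, total in zip(system.moieties, system.totals):
                value = sum(g * c_full[system.row(s)] for s, g in m.items())
                assert value == pytest.approx(total, rel=1e-12)

    def test_missing_c0_for_moiety_member(self, hepg2):
        system = ll.stoichiometric_matrix(hepg2)
        c0 = {s: 1.0 for s in hepg2.balanced_ids if s != "NADH_in"}
        with pytest.raises(ValueError, match="NADH_in"):
            ll.reduce_system(system, c0)

    def test_demotion_changes_row_count_by_one(self, hepg2):
        base = ll.stoichiometric_matrix(hepg2).N.shape[0]
        species = [ll.Species(id=s.id, name=s.name, compartment="boundary",
                              balanced=False)
                   if s.id == "GLU_in" else s for s in hepg2.species]
        model = ll.NetworkModel(species=species, reactions=hepg2.reactions)
        assert ll.stoichiometric_matrix(model).N.shape[0] == base - 1


class TestStructuralReport:
    def test_packaged_counts(self, hepg2):
        report = ll.structural_report(hepg2)
        assert report["reactions"] == 49
        assert report["transport_steps"] == 5
        assert report["transport_ids"] == ["r45", "r46", "r47", "r48", "r49"]
        assert report["inhibitions"] == 21
        assert report["activations"] == 10
        assert report["regulatory_effects"] == 31
        assert report["moieties"] == 3
        assert report["elasticity_pattern_size"] == 174
        assert report["dead_ends"] == []

    def test_dead_end_listed(self):
        model = ll.NetworkModel(
            species=[ll.Species(id="A"), ll.Species(id="B"),
                     ll.Species(id="S", compartment="boundary",
                                balanced=False)],
            reactions=[
                ll.Reaction(id="r1", stoichiometry={"S": -1, "A": 1}),
                ll.Reaction(id="r2", stoichiometry={"A": -1, "B": 1})])
        report = ll.structural_report(model)
        assert report["dead_ends"] == ["B"]


class TestBuildReduction:
    def test_dependent_is_last_member(self, hepg2):
        system = ll.stoichiometric_matrix(hepg2)
        moieties = ll.conserved_moieties(system)
        ind, dep, *_ = _build_reduction(
            system.balanced_ids, system.N, moieties,
            {s: 1.0 for s in system.balanced_ids})
        assert dep == ["AMP_in", "NADH_in", "NADPH_in"]
        assert len(ind) == 42
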