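import collections

import numpy as np
import pandas as pd
import pytest

import linlogccm as ll
from linlogccm.io import load_printed_partial_fcc
from linlogccm.linlog import LinlogSystem

from conftest import chain2_param, oscillator_model, supply_demand_param


def finite_difference_control(model, p, enzymes, delta=1e-5):
    """Independent oracle: perturb each enzyme by x(1 +/- delta), re-solve
    the steady state, and difference ln J and ln c."""
    sys_ = LinlogSystem(model, p)
    dln = np.log(1 + delta) - np.log(1 - delta)
    CJ, CS = {}, {}
    for rid in enzymes:
        up = LinlogSystem(model, p.with_enzyme(rid, 1 + delta))
        dn = LinlogSystem(model, p.with_enzyme(rid, 1 - delta))
        cu, cd = up.steady_state(), dn.steady_state()
        ru, rd = up.rates(cu), dn.rates(cd)
        CJ[rid] = (np.log(np.abs(ru)) - np.log(np.abs(rd))) / dln
        order = {s: i for i, s in enumerate(sys_.balanced_ids)}
        rows = [order[s] for s in model.intracellular_ids]
        CS[rid] = (np.log(cu[rows]) - np.log(cd[rows])) / dln
    return CJ, CS


class TestJacobian:
    def test_one_species_hand_value(self):
        model, p = supply_demand_param(eps_supply=None, eps_demand=0.5,
                                       J0=1.0, c0=2.0)
        jac = ll.jacobian(model, p)
        assert jac.matrix.to_numpy()[0, 0] == pytest.approx(-0.25, rel=1e-12)
        assert jac.stable
        assert jac.conjugate_pairs == 0

    def test_decoupled_negative_diagonal_stable(self):
        model, p = chain2_param()
        jac = ll.jacobian(model, p)
        assert jac.stable

    def test_damped_oscillator_pair(self):
        model, p = oscillator_model()
        jac = ll.jacobian(model, p)
        ev = sorted(jac.eigenvalues, key=lambda z: z.imag)
        assert jac.conjugate_pairs == 1
        assert all(z.real < 0 for z in ev)
        assert ev[-1] == pytest.approx(-1 + 2j, rel=1e-12)

    def test_packaged_stable_by_construction(self, hepg2, hepg2_truth):
        jac = ll.jacobian(hepg2, hepg2_truth)
        assert jac.stable
        assert jac.matrix.shape == (42, 42)


class TestControlCoefficients:
    def test_summation_theorems_toys(self):
        for model, p in (chain2_param(), oscillator_model()):
            C_S, C_J = ll.control_coefficients(model, p)
            assert np.abs(C_J.sum(axis=1) - 1).max() < 1e-8
            assert np.abs(C_S.sum(axis=1)).max() < 1e-8

    def test_summation_theorems_packaged(self, hepg2, hepg2_truth):
        C_S, C_J = ll.control_coefficients(hepg2, hepg2_truth)
        assert np.abs(C_J.sum(axis=1) - 1).max() < 1e-8
        assert np.abs(C_S.sum(axis=1)).max() < 1e-8

    def test_supply_demand_closed_form(self):
        eps_s, eps_d = -1.0, 1.0
        model, p = supply_demand_param(eps_supply=eps_s, eps_demand=eps_d)
        _, C_J = ll.control_coefficients(model, p)
        assert C_J.loc["supply", "supply"] == pytest.approx(
            eps_d / (eps_d - eps_s), rel=1e-12)

    def test_finite_difference_oracle_toys(self):
        for model, p in (chain2_param(), oscillator_model()):
            C_S, C_J = ll.control_coefficients(model, p)
            CJ_fd, CS_fd = finite_difference_control(
                model, p, model.reaction_ids)
            for rid in model.reaction_ids:
                cj = C_J[rid].to_numpy()
                mask = np.abs(cj) > 1e-3
                if mask.any():
                    assert np.abs((CJ_fd[rid][mask] - cj[mask])
                                  / cj[mask]).max() < 1e-3
                cs = C_S[rid].to_numpy()
                mask = np.abs(cs) > 1e-3
                if mask.any():
                    assert np.abs((CS_fd[rid][mask] - cs[mask])
                                  / cs[mask]).max() < 1e-3

    def test_singular_control_problem_raises(self):
        # zero elasticities: M is identically zero
        model, p = supply_demand_param(eps_supply=None, eps_demand=None)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            ll.control_coefficients(model, p)


class TestPartialFluxControl:
    def test_printed_off_diagonal_row_sums_to_total(self):
        table = load_printed_partial_fcc()
        row = table[(table.flux_id == "r2") & (table.enzyme_id == "r10")]
        total = ll.fcc_from_partials(row.value.tolist(), self_flux=False)
        assert total == pytest.approx(-1.63, abs=1e-12)

    def test_printed_diagonal_includes_direct_term(self):
        table = load_printed_partial_fcc()
        row = table[(table.flux_id == "r2") & (table.enzyme_id == "r2")]
        total = ll.fcc_from_partials(row.value.tolist(), self_flux=True)
        assert total == pytest.approx(0.11, abs=1e-12)

    @pytest.mark.parametrize("flux,enzyme,expected", [
        ("r18", "r41", 0.718),
        ("r43", "r22", 1.287),
    ])
    def test_printed_blocks(self, flux, enzyme, expected):
        table = load_printed_partial_fcc()
        row = table[(table.flux_id == flux) & (table.enzyme_id == enzyme)]
        assert len(row) == 4
        total = ll.fcc_from_partials(row.value.tolist(), self_flux=False)
        assert total == pytest.approx(expected, abs=1e-12)

    def test_decomposition_identity_packaged(self, hepg2, hepg2_truth):
        C_S, C_J = ll.control_coefficients(hepg2, hepg2_truth)
        pfcc = ll.partial_flux_control(hepg2, hepg2_truth, C_S)
        sums = collections.defaultdict(float)
        for (i, j, _x), v in pfcc.items():
            sums[(i, j)] += v
        rebuilt = pd.DataFrame(np.eye(49), index=C_J.index,
                               columns=C_J.columns)
        for (i, j), v in sums.items():
            rebuilt.loc[i, j] += v
        assert (C_J - rebuilt).abs().to_numpy().max() < 1e-8

    def test_single_mediator_partial_equals_total_minus_direct(self):
        model, p = supply_demand_param(eps_supply=-0.5, eps_demand=1.0)
        C_S, C_J = ll.control_coefficients(model, p)
        pfcc = ll.partial_flux_control(model, p, C_S)
        for j in model.reaction_ids:
            delta = 1.0 if j == "demand" else 0.0
            assert pfcc[("demand", j, "X_in")] == pytest.approx(
                C_J.loc["demand", j] - delta, rel=1e-12)


class TestInternalResponse:
    def test_connectivity_sums_to_minus_one(self, hepg2, hepg2_truth):
        result = ll.analyze(hepg2, hepg2_truth)
        sums = collections.defaultdict(float)
        for (x, _j), v in result.irc.items():
            sums[x] += v
        non_moiety = set(hepg2.intracellular_ids) - set(
            result.excluded_species)
        assert set(sums) == non_moiety
        for x, total in sums.items():
            assert total == pytest.approx(-1.0, abs=1e-6)

    def test_moiety_members_excluded(self, hepg2, hepg2_truth):
        result = ll.analyze(hepg2, hepg2_truth)
        assert sorted(result.excluded_species) == [
            "ADP_in", "AMP_in", "ATP_in", "NADH_in", "NADPH_in",
            "NADP_in", "NAD_in"]
        assert not any(x in result.excluded_species
                       for (x, _j) in result.irc)

    def test_irc_is_diagonal_partial(self, hepg2, hepg2_truth):
        # independent recomputation path: eps * C_S directly
        C_S, _ = ll.control_coefficients(hepg2, hepg2_truth)
        result = ll.analyze(hepg2, hepg2_truth)
        for (x, j), v in list(result.irc.items())[::37]:
            eps = hepg2_truth.elasticities[(j, x)]
            assert v == eps * C_S.loc[x, j]

    def test_sign_of_sole_consumer(self):
        # species consumed by one reaction with positive substrate
        # elasticity: that reaction's irc must be negative
        model, p = supply_demand_param(eps_supply=-0.5, eps_demand=1.0)
        result = ll.analyze(model, p)
        assert result.irc[("X_in", "demand")] < 0


class TestReport:
    def test_report_files_and_round_trip(self, hepg2, hepg2_truth, tmp_path):
        result = ll.analyze(hepg2, hepg2_truth)
        paths = ll.mca_report(result, hepg2, tmp_path)
        fcc = pd.read_csv(paths["fcc"], sep="\t", index_col=0,
                          float_precision="round_trip")
        assert list(fcc.columns) == [f"r{i}" for i in range(1, 50)]
        assert np.allclose(fcc.to_numpy(), result.C_J.to_numpy(),
                           rtol=0, atol=0)
        ev = pd.read_csv(paths["eigenvalues"], sep="\t")
        assert len(ev) == 42

    def test_empty_result_rejected(self, hepg2, hepg2_truth, tmp_path):
        result = ll.analyze(hepg2, hepg2_truth)
        result.C_J = pd.DataFrame()
        with pytest.raises(ValueError):
            ll.mca_report(result, hepg2, tmp_path)
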