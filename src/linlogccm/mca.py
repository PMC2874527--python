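"""Metabolic control analysis of a linlog parameterization.

Implements, at the reference state:

* the Jacobian of the reduced system and its eigenvalue/stability analysis,
* scaled concentration and flux control coefficients,
* partial flux control coefficients (unscaled single-mediator summands), and
* partial internal response coefficients.

Steady-state (control) quantities are computed on the intracellular
subsystem; extracellular pools are exchange pools of a batch culture and act
as fixed external effectors at steady state.  The dynamic Jacobian used for
the stability flag covers the full reduced system, extracellular species
included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .linlog import LinlogSystem, Parameterization
from .network import NetworkModel

#: condition number above which the control problem is rejected as singular
MAX_CONDITION = 1e12

#: tolerance used when pairing complex-conjugate eigenvalues
PAIRING_TOL = 1e-9


@dataclass
class JacobianResult:
    matrix: pd.DataFrame          # independent x independent, 1/min
    eigenvalues: np.ndarray
    stable: bool
    conjugate_pairs: int


@dataclass
class ControlAnalysisResult:
    jacobian: JacobianResult
    C_S: pd.DataFrame             # intracellular balanced species x reactions
    C_J: pd.DataFrame             # reactions x reactions
    partial_fcc: dict[tuple[str, str, str], float]
    irc: dict[tuple[str, str], float]
    excluded_species: list[str]   # moiety members (no irc defined)


def _count_conjugate_pairs(eigenvalues: np.ndarray) -> int:
    ev = sorted(eigenvalues, key=lambda z: (z.real, abs(z.imag)))
    used = [False] * len(ev)
    pairs = 0
    for i, z in enumerate(ev):
        if used[i] or abs(z.imag) <= PAIRING_TOL:
            continue
        for j in range(i + 1, len(ev)):
            if not used[j] and abs(ev[j] - np.conj(z)) <= PAIRING_TOL * max(
                    1.0, abs(z)):
                used[i] = used[j] = True
                pairs += 1
                break
    return pairs


def jacobian(model: NetworkModel, p: Parameterization,
             sys_: LinlogSystem | None = None) -> JacobianResult:
    """Jacobian N_R diag(J0) E diag(c0)^-1 L of the full reduced system."""
    sys_ = sys_ or LinlogSystem(model, p)
    system = sys_.system
    J = system.N_R @ np.diag(sys_.e * sys_.J0) @ sys_.E @ np.diag(
        1.0 / sys_.c0) @ system.L
    ev = np.linalg.eigvals(J)
    return JacobianResult(
        matrix=pd.DataFrame(J, index=system.independent_ids,
                            columns=system.independent_ids),
        eigenvalues=ev,
        stable=bool(ev.real.max() < 0),
        conjugate_pairs=_count_conjugate_pairs(ev),
    )


def _mca_matrices(sys_: LinlogSystem):
    """Intracellular reduced matrices entering the control formulas."""
    order = {s: i for i, s in enumerate(sys_.balanced_ids)}
    int_rows = [order[s] for s in sys_.intracellular_ids]
    E_int = sys_.E[:, int_rows]
    c0_int = sys_.c0[int_rows]
    NR = sys_.NR_int
    L = sys_.L_int
    M = NR @ np.diag(sys_.e * sys_.J0) @ E_int @ np.diag(1.0 / c0_int) @ L
    return NR, L, E_int, c0_int, M


def control_coefficients(model: NetworkModel, p: Parameterization,
                         sys_: LinlogSystem | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scaled concentration (C_S) and flux (C_J) control coefficients.

    C_S = diag(c0)^-1 (-L M^-1 N_R diag(J0)),  C_J = I + E C_S, with
    M = N_R diag(J0) E diag(c0)^-1 L over the intracellular subsystem.
    Coefficients are with respect to relative enzyme-activity changes.
    """
    sys_ = sys_ or LinlogSystem(model, p)
    NR, L, E_int, c0_int, M = _mca_matrices(sys_)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        rank = int(np.linalg.matrix_rank(M))
        raise np.linalg.LinAlgError(
            f"structurally singular control problem: cond(M) = {cond:.3g}, "
            f"rank {rank}/{M.shape[0]}")
    CS = np.diag(1.0 / c0_int) @ (
        -L @ np.linalg.solve(M, NR @ np.diag(sys_.e * sys_.J0)))
    CJ = np.eye(len(sys_.reaction_ids)) + E_int @ CS
    C_S = pd.DataFrame(CS, index=sys_.intracellular_ids,
                       columns=sys_.reaction_ids)
    C_J = pd.DataFrame(CJ, index=sys_.reaction_ids, columns=sys_.reaction_ids)
    return C_S, C_J


def partial_flux_control(model: NetworkModel, p: Parameterization,
                         C_S: pd.DataFrame
                         ) -> dict[tuple[str, str, str], float]:
    """Unscaled partial flux control coefficients eps[i,x] * C_S[x,j].

    Keys are (flux i, enzyme j, mediator x) for every in-pattern (i, x) with
    x an intracellular balanced species.
    """
    intra = set(C_S.index)
    out: dict[tuple[str, str, str], float] = {}
    CS = C_S.to_numpy()
    srow = {s: k for k, s in enumerate(C_S.index)}
    for (rid, sid), eps in p.elasticities.values.items():
        if sid not in intra:
            continue
        row = CS[srow[sid]]
        for j, enz in enumerate(C_S.columns):
            out[(rid, enz, sid)] = eps * row[j]
    return out


def fcc_from_partials(partials, self_flux: bool) -> float:
    """Total flux control coefficient from its mediator partials.

    The decomposition C_J[i, j] = delta_ij + sum_x pfcc[i, j, x]: the direct
    term contributes 1 exactly when the enzyme acts on its own flux.
    """
    vals = partials.values() if isinstance(partials, dict) else partials
    return (1.0 if self_flux else 0.0) + float(sum(vals))


def internal_response(model: NetworkModel, p: Parameterization,
                      partial_fcc: dict[tuple[str, str, str], float]
                      ) -> tuple[dict[tuple[str, str], float], list[str]]:
    """Partial internal response coefficients irc[x, j] = pfcc[j, j, x].

    Species belonging to conserved moieties are excluded (a perturbation in a
    conserved pool cannot be counteracted back to the original steady state);
    they are returned separately as not-applicable.
    """
    sys_ = LinlogSystem(model, p)
    moiety_members = sorted({s for m in sys_.system.moieties for s in m})
    excluded = set(moiety_members)
    irc: dict[tuple[str, str], float] = {}
    for (i, j, x), v in partial_fcc.items():
        if i == j and x not in excluded:
            irc[(x, j)] = v
    return irc, moiety_members


def analyze(model: NetworkModel, p: Parameterization) -> ControlAnalysisResult:
    """Full control analysis pipeline for a parameterization."""
    sys_ = LinlogSystem(model, p)
    jac = jacobian(model, p, sys_=sys_)
    C_S, C_J = control_coefficients(model, p, sys_=sys_)
    pfcc = partial_flux_control(model, p, C_S)
    irc, excluded = internal_response(model, p, pfcc)
    return ControlAnalysisResult(jacobian=jac, C_S=C_S, C_J=C_J,
                                 partial_fcc=pfcc, irc=irc,
                                 excluded_species=excluded)


def mca_report(result: ControlAnalysisResult, model: NetworkModel,
               outdir: str | Path) -> dict[str, Path]:
    """Write fcc/ccc/partial-fcc/irc/eigenvalue tables to *outdir*."""
    if result.C_J.empty:
        raise ValueError("empty control-analysis result")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["fcc"] = outdir / "fcc.tsv"
    result.C_J.to_csv(paths["fcc"], sep="\t", float_format="%.17g",
                      index_label="flux_id")
    paths["ccc"] = outdir / "ccc.tsv"
    result.C_S.to_csv(paths["ccc"], sep="\t", float_format="%.17g",
                      index_label="species_id")
    paths["partial_fcc"] = outdir / "partial_fcc.tsv"
    pf = pd.DataFrame(
        [(i, j, x, v) for (i, j, x), v in result.partial_fcc.items()],
        columns=["flux_id", "enzyme_id", "mediator_id", "value"])
    pf.to_csv(paths["partial_fcc"], sep="\t", index=False,
              float_format="%.17g")
    paths["irc"] = outdir / "irc.tsv"
    ir = pd.DataFrame(
        [(x, j, v) for (x, j), v in result.irc.items()],
        columns=["species_id", "enzyme_id", "value"])
    ir.to_csv(paths["irc"], sep="\t", index=False, float_format="%.17g")
    paths["eigenvalues"] = outdir / "eigenvalues.tsv"
    ev = pd.DataFrame({"re": result.jacobian.eigenvalues.real,
                       "im": result.jacobian.eigenvalues.imag})
    ev.to_csv(paths["eigenvalues"], sep="\t", index=False,
              float_format="%.17g")
    return paths
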