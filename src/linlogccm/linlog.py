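"""Linlog rate law and integration of the normalized mass balances.

Each reaction rate is anchored at a reference state (J0, c0):

    r_i = (e_i/e0_i) * J0_i * (1 + sum_x eps[i, x] * ln(c_x / c0_x))

with scaled elasticities eps restricted to a sparsity pattern (balanced
substrates and products of each reaction plus its declared modifiers).
Conservation relations are eliminated algebraically: integration runs on the
independent species, dependent moiety members being reconstructed from the
totals at every step.

The reference flux distribution is a steady state of the *intracellular*
subsystem; extracellular pools are exchange pools of a batch culture and may
drift at the reference state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import (NetworkModel, StoichiometricSystem, _build_reduction,
                      conserved_moieties, reduce_system, stoichiometric_matrix)

logger = logging.getLogger(__name__)

DEFAULT_TIME_GRID = (0.0, 1.0, 2.0, 5.0, 10.0, 30.0, 60.0, 120.0, 180.0)

#: floor applied inside the logarithm (the rate law diverges as c -> 0)
LOG_CLAMP = 1e-6


def elasticity_pattern(model: NetworkModel) -> list[tuple[str, str]]:
    """Sparsity pattern of the scaled elasticity matrix.

    One entry per (reaction, balanced substrate-or-product) pair — counted
    once per species per reaction regardless of stoichiometric coefficient —
    plus one per modifier link.  Boundary species carry no elasticity.
    """
    balanced = set(model.balanced_ids)
    pattern: list[tuple[str, str]] = []
    for r in model.reactions:
        seen: set[str] = set()
        for sid in r.stoichiometry:
            if sid in balanced and sid not in seen:
                pattern.append((r.id, sid))
                seen.add(sid)
        for sid in r.modifiers:
            if sid in balanced and sid not in seen:
                pattern.append((r.id, sid))
                seen.add(sid)
    return pattern


@dataclass
class ElasticityMatrix:
    """Sparse scaled-elasticity table over an explicit sparsity pattern."""

    pattern: list[tuple[str, str]]
    values: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = set(self.pattern)
        for key in self.values:
            if key not in allowed:
                raise ValueError(f"elasticity {key} outside sparsity pattern")

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.values.get(key, 0.0)

    def set(self, rid: str, sid: str, value: float) -> None:
        if (rid, sid) not in set(self.pattern):
            raise ValueError(f"elasticity ({rid}, {sid}) outside pattern")
        self.values[(rid, sid)] = float(value)

    def dense(self, reaction_ids: list[str],
              species_ids: list[str]) -> np.ndarray:
        """Dense reactions x species matrix (structural zeros elsewhere)."""
        E = np.zeros((len(reaction_ids), len(species_ids)))
        ri = {r: i for i, r in enumerate(reaction_ids)}
        si = {s: i for i, s in enumerate(species_ids)}
        for (rid, sid), v in self.values.items():
            if rid in ri and sid in si:
                E[ri[rid], si[sid]] = v
        return E

    @classmethod
    def from_model(cls, model: NetworkModel,
                   values: dict[tuple[str, str], float] | None = None
                   ) -> "ElasticityMatrix":
        return cls(pattern=elasticity_pattern(model), values=values or {})


@dataclass
class ReferenceState:
    """Reference steady-state fluxes J0 and concentrations c0."""

    J0: dict[str, float]
    c0: dict[str, float]

    def __post_init__(self) -> None:
        for sid, c in self.c0.items():
            if not c > 0:
                raise ValueError(f"reference concentration of {sid} must be > 0")

    def check_steady_state(self, model: NetworkModel,
                           rtol: float = 1e-8) -> None:
        """Verify N_int . J0 = 0 over the intracellular balanced species."""
        system = stoichiometric_matrix(model)
        rows = [system.row(s) for s in model.intracellular_ids]
        J = np.array([self.J0[r] for r in model.reaction_ids])
        resid = np.abs(system.N[rows, :] @ J).max()
        scale = max(np.abs(J).max(), 1.0)
        if resid > rtol * scale:
            raise ValueError(
                f"J0 is not an intracellular steady state (residual {resid:g})")


@dataclass
class Parameterization:
    elasticities: ElasticityMatrix
    reference: ReferenceState
    enzyme_levels: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, e in self.enzyme_levels.items():
            if e < 0:
                raise ValueError(f"enzyme level of {rid} must be >= 0")

    def enzyme_vector(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.enzyme_levels.get(r, 1.0) for r in reaction_ids])

    def with_enzyme(self, rid: str, level: float) -> "Parameterization":
        levels = dict(self.enzyme_levels)
        levels[rid] = level
        return Parameterization(elasticities=self.elasticities,
                                reference=self.reference,
                                enzyme_levels=levels)


@dataclass
class PerturbationDesign:
    """Extracellular reset applied at t = 0 plus the sampling layout."""

    post_perturbation_extracellular: dict[str, float]
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    observed: list[str] = field(default_factory=list)
    replicates: int = 3

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.time_grid)
        if grid[0] != 0.0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("time grid must start at 0 and strictly increase")
        self.time_grid = grid
        for sid, c in self.post_perturbation_extracellular.items():
            if c < 0:
                raise ValueError(
                    f"post-perturbation level of {sid} must be >= 0")


@dataclass
class Trajectory:
    times: np.ndarray
    species_ids: list[str]
    values: np.ndarray  # times x species, normalized c/c0

    def series(self, sid: str) -> np.ndarray:
        return self.values[:, self.species_ids.index(sid)]

    def at(self, t: float) -> np.ndarray:
        idx = np.nonzero(np.isclose(self.times, t))[0]
        if idx.size == 0:
            raise KeyError(f"time {t} not in trajectory")
        return self.values[idx[0]]

    def to_frame(self, model: NetworkModel | None = None):
        import pandas as pd
        comp = {}
        if model is not None:
            comp = {s.id: s.compartment for s in model.species}
        rows = []
        for i, t in enumerate(self.times):
            for j, sid in enumerate(self.species_ids):
                rows.append((t, sid, comp.get(sid, ""), self.values[i, j]))
        return pd.DataFrame(
            rows, columns=["time_min", "species_id", "compartment",
                           "value_normalized"])


class LinlogSystem:
    """Compiled linlog model: dense arrays for fast evaluation."""

    def __init__(self, model: NetworkModel, param: Parameterization,
                 clamp: float = LOG_CLAMP):
        self.model = model
        self.param = param
        self.clamp = clamp
        self.reaction_ids = model.reaction_ids
        system = stoichiometric_matrix(model)
        reduce_system(system, c0=param.reference.c0)
        self.system: StoichiometricSystem = system
        self.balanced_ids = system.balanced_ids
        self.independent_ids = system.independent_ids
        self.E = param.elasticities.dense(self.reaction_ids, self.balanced_ids)
        self.J0 = np.array([param.reference.J0[r] for r in self.reaction_ids])
        self.c0 = np.array([param.reference.c0[s] for s in self.balanced_ids])
        self.e = param.enzyme_vector(self.reaction_ids)
        self.c0_ind = np.array(
            [param.reference.c0[s] for s in self.independent_ids])
        self._clamp_warned: set[str] = set()
        self._refresh_cache()
        pattern = param.elasticities.pattern
        ri = {r: i for i, r in enumerate(self.reaction_ids)}
        si = {s: i for i, s in enumerate(self.balanced_ids)}
        self._pattern_rows = np.array([ri[r] for r, _ in pattern], dtype=int)
        self._pattern_cols = np.array([si[s] for _, s in pattern], dtype=int)
        # intracellular sub-reduction used by steady-state analyses
        intra = model.intracellular_ids
        (self.ind_int, self.dep_int, self.NR_int, self.L_int,
         self.off_int, _) = _build_reduction(
            intra, system.N[[system.row(s) for s in intra], :],
            system.moieties, param.reference.c0)
        self.intracellular_ids = intra

    def _refresh_cache(self) -> None:
        self._eJ0 = self.e * self.J0
        self._inv_c0 = 1.0 / self.c0
        self._inv_c0_ind = 1.0 / self.c0_ind

    def set_parameters(self, eps_values: np.ndarray,
                       c0_vec: np.ndarray) -> None:
        """Rebind elasticities (aligned with the pattern) and reference
        concentrations (aligned with ``balanced_ids``) without rebuilding the
        stoichiometric reduction.  Used by the fitting hot loop."""
        self.E[self._pattern_rows, self._pattern_cols] = eps_values
        self.c0 = np.asarray(c0_vec, dtype=float)
        order = {s: i for i, s in enumerate(self.balanced_ids)}
        self.c0_ind = self.c0[[order[s] for s in self.independent_ids]]
        for m, dep in zip(self.system.moieties, self.system.dependent_ids):
            T = sum(g * self.c0[order[s]] for s, g in m.items())
            self.system.offsets[order[dep]] = T / m[dep]
        int_order = {s: i for i, s in enumerate(self.intracellular_ids)}
        for m, dep in zip(self.system.moieties, self.dep_int):
            T = sum(g * self.c0[order[s]] for s, g in m.items())
            self.off_int[int_order[dep]] = T / m[dep]
        self._refresh_cache()

    # -- rate law ----------------------------------------------------------
    def rates(self, c_hat: np.ndarray) -> np.ndarray:
        """Linlog rates for a normalized concentration vector."""
        if not np.all(np.isfinite(c_hat)):
            raise ValueError("non-finite normalized concentration")
        clamped = np.maximum(c_hat, self.clamp)
        if np.any(c_hat < self.clamp):
            for i in np.nonzero(c_hat < self.clamp)[0]:
                sid = self.balanced_ids[i]
                if sid not in self._clamp_warned:
                    self._clamp_warned.add(sid)
                    logger.warning(
                        "clamping ln-argument of %s at %g", sid, self.clamp)
        return self.e * self.J0 * (1.0 + self.E @ np.log(clamped))

    def full_from_independent(self, c_hat_ind: np.ndarray) -> np.ndarray:
        c_ind = c_hat_ind * self.c0_ind
        c_full = self.system.L @ c_ind + self.system.offsets
        return c_full / self.c0

    def _rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        if not np.all(np.abs(y) < 1e9):
            raise FloatingPointError("runaway trajectory")
        c_hat = (self.system.L @ (y * self.c0_ind)
                 + self.system.offsets) * self._inv_c0
        np.maximum(c_hat, self.clamp, out=c_hat)
        r = self._eJ0 * (1.0 + self.E @ np.log(c_hat))
        return (self.system.N_R @ r) * self._inv_c0_ind

    def _jac(self, t: float, y: np.ndarray) -> np.ndarray:
        c_hat = self.full_from_independent(y)
        active = c_hat > self.clamp  # clamped species: zero local derivative
        c = np.where(active, c_hat, np.inf) * self.c0  # concentration units
        # d r_i / d y_k with r depending on ln(c_hat): L * c0_ind / c
        dr = (self.e * self.J0)[:, None] * (
            self.E @ (self.system.L * self.c0_ind[None, :] / c[:, None]))
        return (self.system.N_R @ dr) / self.c0_ind[:, None]

    # -- integration -------------------------------------------------------
    def simulate(self, init: np.ndarray, time_grid,
                 rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
        """Integrate from a full normalized state over *time_grid* (minutes)."""
        init = np.asarray(init, dtype=float)
        if init.shape != (len(self.balanced_ids),):
            raise ValueError("initial state must cover all balanced species")
        # moiety totals implied by the initial state
        offsets_save = self.system.offsets.copy()
        try:
            order = {s: i for i, s in enumerate(self.balanced_ids)}
            for m, dep in zip(self.system.moieties, self.system.dependent_ids):
                T = sum(g * init[order[s]] * self.c0[order[s]]
                        for s, g in m.items())
                self.system.offsets[order[dep]] = T / m[dep]
            ind_rows = [order[s] for s in self.independent_ids]
            y0 = init[ind_rows]
            t = np.asarray(time_grid, dtype=float)
            sol = solve_ivp(self._rhs, (t[0], t[-1]), y0, t_eval=t,
                            method="LSODA", jac=self._jac,
                            rtol=rtol, atol=atol)
            if not sol.success:
                raise RuntimeError(
                    f"integration failed at t = {sol.t[-1] if sol.t.size else t[0]:g}"
                    f" min: {sol.message}")
            values = np.empty((t.size, len(self.balanced_ids)))
            for k in range(t.size):
                values[k] = self.full_from_independent(sol.y[:, k])
            return Trajectory(times=t, species_ids=list(self.balanced_ids),
                              values=values)
        finally:
            self.system.offsets = offsets_save

    # -- intracellular steady state ---------------------------------------
    def full_from_intracellular(self, c_int_ind: np.ndarray,
                                c_hat_ex: np.ndarray) -> np.ndarray:
        """Assemble the full normalized vector from intracellular independents
        and fixed extracellular levels (concentration units internally)."""
        c_int = self.L_int @ c_int_ind + self.off_int
        c_full = np.empty(len(self.balanced_ids))
        order = {s: i for i, s in enumerate(self.balanced_ids)}
        for i, sid in enumerate(self.intracellular_ids):
            c_full[order[sid]] = c_int[i]
        for i, sid in enumerate(self.model.extracellular_ids):
            c_full[order[sid]] = c_hat_ex[i] * self.c0[order[sid]]
        return c_full / self.c0

    def steady_state(self, extracellular: dict[str, float] | None = None,
                     tol: float = 1e-10, max_iter: int = 200
                     ) -> np.ndarray:
        """Solve the intracellular steady state by damped Newton.

        Extracellular levels are held fixed (normalized; default 1).  Returns
        the full normalized concentration vector.  Falls back to a long-time
        integration when Newton stalls; raises on singular Jacobians or
        runaway (unstable) dynamics.
        """
        ex_ids = self.model.extracellular_ids
        c_hat_ex = np.array([1.0 if extracellular is None
                             else extracellular.get(s, 1.0) for s in ex_ids])
        c0_int_ind = np.array([self.param.reference.c0[s]
                               for s in self.ind_int])
        x = c0_int_ind.copy()  # concentrations of intracellular independents
        Jscale = max(np.abs(self.J0).max(), 1.0)

        def residual(xv):
            c_hat = self.full_from_intracellular(xv, c_hat_ex)
            return self.NR_int @ self.rates(c_hat)

        order = {s: i for i, s in enumerate(self.balanced_ids)}
        int_rows = [order[s] for s in self.intracellular_ids]

        def newton_jac(xv):
            c_hat = self.full_from_intracellular(xv, c_hat_ex)
            active = c_hat > self.clamp
            c_full = np.where(active, c_hat, np.inf) * self.c0
            E_int = self.E[:, int_rows]
            dr = (self.e * self.J0)[:, None] * (
                E_int @ (self.L_int / c_full[int_rows][:, None]))
            return self.NR_int @ dr

        def check_stable(xv):
            # the intracellular dynamic Jacobian (concentration space) is the
            # Newton Jacobian itself; a positive real part means the solved
            # fixed point repels trajectories
            ev = np.linalg.eigvals(newton_jac(xv))
            if ev.real.max() >= 0:
                raise RuntimeError(
                    "steady state is unstable (runaway trajectory from any "
                    "perturbation)")

        f = residual(x)
        for _ in range(max_iter):
            if np.abs(f).max() < tol * Jscale:
                check_stable(x)
                return self.full_from_intracellular(x, c_hat_ex)
            J = newton_jac(x)
            try:
                step = np.linalg.solve(J, -f)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(
                    "singular Jacobian in steady-state solve") from exc
            lam, ok = 1.0, False
            fnorm = np.abs(f).max()
            for _ in range(40):
                x_new = x + lam * step
                if np.all(x_new > 0):
                    f_new = residual(x_new)
                    if np.abs(f_new).max() < fnorm:
                        x, f, ok = x_new, f_new, True
                        break
                lam *= 0.5
            if not ok:
                break
        if np.abs(f).max() < tol * Jscale:
            check_stable(x)
            return self.full_from_intracellular(x, c_hat_ex)
        # fallback: integrate toward the attractor, then polish
        init = self.full_from_intracellular(x, c_hat_ex)
        try:
            traj = self.simulate(init, (0.0, 1e3, 1e4), rtol=1e-10, atol=1e-12)
        except RuntimeError as exc:
            raise RuntimeError(
                "steady-state solve diverged (runaway trajectory)") from exc
        end = traj.values[-1]
        if np.abs(end).max() > 1e6:
            raise RuntimeError(
                "steady-state solve diverged (runaway trajectory)")
        x = np.array([end[order[s]] * self.c0[order[s]] for s in self.ind_int])
        f = residual(x)
        for _ in range(max_iter):
            if np.abs(f).max() < tol * Jscale:
                check_stable(x)
                return self.full_from_intracellular(x, c_hat_ex)
            step = np.linalg.solve(newton_jac(x), -f)
            x = np.maximum(x + step, 1e-12)
            f = residual(x)
        raise RuntimeError(
            f"steady-state solve did not converge (residual {np.abs(f).max():g})")


# ---------------------------------------------------------------------------
# functional front-ends
# ---------------------------------------------------------------------------

def rates(model: NetworkModel, p: Parameterization,
          c_hat: np.ndarray | dict[str, float]) -> dict[str, float]:
    sys_ = LinlogSystem(model, p)
    if isinstance(c_hat, dict):
        vec = np.array([c_hat[s] for s in sys_.balanced_ids])
    else:
        vec = np.asarray(c_hat, dtype=float)
    r = sys_.rates(vec)
    return dict(zip(sys_.reaction_ids, r))


def initial_state(model: NetworkModel, design: PerturbationDesign,
                  ref: ReferenceState) -> np.ndarray:
    """Normalized state right after the medium exchange.

    Intracellular species at 1; extracellular at c_post/c0 (floored at the
    log clamp so a zeroed medium level stays representable).
    """
    balanced = model.balanced_ids
    state = np.ones(len(balanced))
    for sid in model.extracellular_ids:
        if sid not in design.post_perturbation_extracellular:
            raise ValueError(
                f"missing post-perturbation level for extracellular {sid}")
        c_post = design.post_perturbation_extracellular[sid]
        state[balanced.index(sid)] = max(c_post / ref.c0[sid], LOG_CLAMP)
    return state


def simulate(model: NetworkModel, p: Parameterization, init: np.ndarray,
             time_grid=DEFAULT_TIME_GRID, rtol: float = 1e-8,
             atol: float = 1e-10) -> Trajectory:
    return LinlogSystem(model, p).simulate(init, time_grid,
                                           rtol=rtol, atol=atol)


def steady_state(model: NetworkModel, p: Parameterization,
                 extracellular: dict[str, float] | None = None,
                 tol: float = 1e-10) -> dict[str, float]:
    sys_ = LinlogSystem(model, p)
    c_hat = sys_.steady_state(extracellular=extracellular, tol=tol)
    return dict(zip(sys_.balanced_ids, c_hat))
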