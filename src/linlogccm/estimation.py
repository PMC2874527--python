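"""Variance-weighted least-squares fitting with a (mu, lambda) evolution
strategy.

The objective is the chi-square sum over all replicate records,
(c_sim - c_meas)^2 / sd^2, evaluated exactly at the measurement times
(no interpolation).  Unknowns are the in-pattern scaled elasticities plus
reference concentrations: unmeasured levels are searched in log space,
measured levels within +/- 3 SD of their pre-stimulus estimates (or held
fixed in ``fix_measured`` mode).  The reference flux distribution J0 is a
fixed input and is never fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .linlog import (ElasticityMatrix, LinlogSystem, Parameterization,
                     PerturbationDesign, ReferenceState, Trajectory,
                     elasticity_pattern, initial_state)
from .network import NetworkModel, stoichiometric_matrix

logger = logging.getLogger(__name__)

#: penalty assigned to candidates whose simulation fails
FAILURE_PENALTY = 1e12

#: relative / absolute floors applied to measurement SDs
SD_REL_FLOOR = 0.05
SD_ABS_FLOOR = 1e-6


@dataclass
class MeasurementSet:
    """Tidy replicate-level time courses plus the pre-stimulus block."""

    COLUMNS = ["time_min", "species_id", "compartment", "replicate",
               "value_normalized", "sd_normalized"]

    records: pd.DataFrame
    reference_block: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"measurement table lacks columns: {missing}")
        rec = self.records.copy()
        rec = rec.astype({"time_min": float, "replicate": int,
                          "value_normalized": float, "sd_normalized": float})
        floor = np.maximum(SD_REL_FLOOR * rec["value_normalized"].abs(),
                           SD_ABS_FLOOR)
        rec["sd_normalized"] = np.maximum(rec["sd_normalized"], floor)
        self.records = rec

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species_id"].unique())

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.records["time_min"].unique())

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False, float_format="%.17g")
        if self.reference_block is not None:
            ref_path = Path(path).with_suffix(".reference.csv")
            self.reference_block.to_csv(ref_path, index=False,
                                        float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementSet":
        records = pd.read_csv(path, float_precision="round_trip")
        ref_path = Path(path).with_suffix(".reference.csv")
        reference = (pd.read_csv(ref_path, float_precision="round_trip")
                     if ref_path.exists() else None)
        return cls(records=records, reference_block=reference)


def chi_squared(sim: Trajectory, data: MeasurementSet) -> float:
    """Variance-weighted sum of squared residuals, replicates individually."""
    total = 0.0
    times = list(sim.times)
    time_index = {}
    for i, t in enumerate(times):
        time_index[round(float(t), 9)] = i
    sp_index = {s: j for j, s in enumerate(sim.species_ids)}
    for row in data.records.itertuples(index=False):
        key = round(float(row.time_min), 9)
        if key not in time_index:
            raise ValueError(
                f"measurement time {row.time_min} min not in trajectory")
        if row.species_id not in sp_index:
            raise ValueError(f"species {row.species_id} not simulated")
        c_sim = sim.values[time_index[key], sp_index[row.species_id]]
        total += ((c_sim - row.value_normalized) / row.sd_normalized) ** 2
    return float(total)


def count_unknowns(model: NetworkModel,
                   data: MeasurementSet | None = None) -> dict:
    """Parameter census: in-pattern elasticities + independent reference
    levels (rank of the balanced stoichiometric matrix)."""
    n_eps = len(elasticity_pattern(model))
    system = stoichiometric_matrix(model)
    n_levels = system.rank
    if data is not None:
        measured = set(data.species)
    else:
        measured = {s.id for s in model.species if s.measured}
    n_measured = len(measured & set(model.balanced_ids))
    return {"elasticities": n_eps,
            "reference_levels": n_levels,
            "total": n_eps + n_levels,
            "measured_reference_levels": n_measured}


@dataclass
class FitOptions:
    mu: int = 10
    lam: int = 70
    budget: int = 20000
    restart_every: int = 100000
    elasticity_bounds: tuple[float, float] = (-20.0, 20.0)
    sign_priors: bool = False
    fix_measured: bool = False
    unknown_c0_log10_bounds: tuple[float, float] = (-3.0, 3.0)
    sigma_init: float = 0.1
    sim_rtol: float = 1e-6
    multi_start: int = 1


@dataclass
class FitResult:
    parameterization: Parameterization
    chi2: float
    evaluations: int
    restarts: int
    seed: int
    trace: list[float] = field(default_factory=list)


class _Problem:
    """Maps the unknown vector to a Parameterization and scores it."""

    def __init__(self, model: NetworkModel, data: MeasurementSet,
                 design: PerturbationDesign, J0: dict[str, float],
                 options: FitOptions):
        self.model = model
        self.data = data
        self.design = design
        self.options = options
        self.J0 = dict(J0)
        for sid in model.extracellular_ids:
            if sid not in design.post_perturbation_extracellular:
                raise ValueError(
                    f"missing post-perturbation level for extracellular {sid}")
        self.pattern = elasticity_pattern(model)
        balanced = model.balanced_ids
        sp = model.species_by_id

        ref_means: dict[str, tuple[float, float]] = {}
        if data.reference_block is not None:
            for row in data.reference_block.itertuples(index=False):
                ref_means[row.species_id] = (row.c0_estimate, row.c0_sd)

        # unknown layout: elasticities first, then free c0 entries
        self.c0_ids: list[str] = []
        self.c0_kind: list[str] = []   # "measured" | "unknown"
        self.c0_fixed: dict[str, float] = {}
        for sid in balanced:
            known = sp[sid].reference_concentration
            measured = sid in ref_means or sp[sid].measured
            if known is not None:
                self.c0_fixed[sid] = known
            elif measured and options.fix_measured:
                self.c0_fixed[sid] = ref_means.get(sid, (1.0, 0.0))[0]
            elif measured:
                self.c0_ids.append(sid)
                self.c0_kind.append("measured")
            else:
                self.c0_ids.append(sid)
                self.c0_kind.append("unknown")
        self.ref_means = ref_means

        lo, hi = [], []
        for rid, sid in self.pattern:
            if options.sign_priors:
                sign = self._prior_sign(rid, sid)
                if sign > 0:
                    lo.append(0.0); hi.append(options.elasticity_bounds[1])
                elif sign < 0:
                    lo.append(options.elasticity_bounds[0]); hi.append(0.0)
                else:
                    lo.append(options.elasticity_bounds[0])
                    hi.append(options.elasticity_bounds[1])
            else:
                lo.append(options.elasticity_bounds[0])
                hi.append(options.elasticity_bounds[1])
        for sid, kind in zip(self.c0_ids, self.c0_kind):
            if kind == "measured":
                mean, sd = self.ref_means.get(sid, (1.0, 0.1))
                sd = max(sd, 1e-6 * abs(mean), 1e-9)
                lo.append(max(mean - 3 * sd, 1e-6))
                hi.append(mean + 3 * sd)
            else:  # log10 concentration
                lo.append(options.unknown_c0_log10_bounds[0])
                hi.append(options.unknown_c0_log10_bounds[1])
        self.lower = np.array(lo)
        self.upper = np.array(hi)
        if np.any(self.lower >= self.upper):
            raise ValueError("infeasible bounds configuration")
        self.n = self.lower.size
        self.n_eps = len(self.pattern)
        self.failures = 0

        # compiled template reused across candidate evaluations
        self._template = LinlogSystem(model, self.decode(self.initial_guess()))
        self._times = data.times
        bal_index = {s: i for i, s in enumerate(self._template.balanced_ids)}
        t_index = {round(float(t), 9): i for i, t in enumerate(self._times)}
        self._obs_t = np.array(
            [t_index[round(float(t), 9)]
             for t in data.records["time_min"]], dtype=int)
        self._obs_s = np.array(
            [bal_index[s] for s in data.records["species_id"]], dtype=int)
        self._obs_val = data.records["value_normalized"].to_numpy()
        self._obs_w = 1.0 / data.records["sd_normalized"].to_numpy()

    def _prior_sign(self, rid: str, sid: str) -> int:
        r = self.model.reactions_by_id[rid]
        if sid in r.activators:
            return 1
        if sid in r.inhibitors:
            return -1
        c = r.stoichiometry.get(sid)
        if c is None:
            return 0
        return 1 if c < 0 else -1  # substrate +, product -

    def decode(self, x: np.ndarray) -> Parameterization:
        values = {key: float(v)
                  for key, v in zip(self.pattern, x[:self.n_eps])}
        c0 = dict(self.c0_fixed)
        for k, (sid, kind) in enumerate(zip(self.c0_ids, self.c0_kind)):
            v = x[self.n_eps + k]
            c0[sid] = float(v) if kind == "measured" else float(10.0 ** v)
        return Parameterization(
            elasticities=ElasticityMatrix(pattern=self.pattern, values=values),
            reference=ReferenceState(J0=self.J0, c0=c0))

    def encode(self, p: Parameterization) -> np.ndarray:
        x = np.zeros(self.n)
        for i, key in enumerate(self.pattern):
            x[i] = p.elasticities.values.get(key, 0.0)
        for k, (sid, kind) in enumerate(zip(self.c0_ids, self.c0_kind)):
            c = p.reference.c0[sid]
            x[self.n_eps + k] = c if kind == "measured" else np.log10(c)
        return np.clip(x, self.lower, self.upper)

    def initial_guess(self) -> np.ndarray:
        x = np.zeros(self.n)
        for k, (sid, kind) in enumerate(zip(self.c0_ids, self.c0_kind)):
            if kind == "measured":
                x[self.n_eps + k] = self.ref_means.get(sid, (1.0, 0.0))[0]
            else:
                x[self.n_eps + k] = 0.0  # 10^0 = 1
        return np.clip(x, self.lower, self.upper)

    def _c0_vector(self, x: np.ndarray) -> np.ndarray:
        sys_ = self._template
        c0 = np.empty(len(sys_.balanced_ids))
        for i, sid in enumerate(sys_.balanced_ids):
            c0[i] = self.c0_fixed.get(sid, np.nan)
        for k, (sid, kind) in enumerate(zip(self.c0_ids, self.c0_kind)):
            v = x[self.n_eps + k]
            c0[sys_.balanced_ids.index(sid)] = (
                v if kind == "measured" else 10.0 ** v)
        return c0

    def objective(self, x: np.ndarray) -> float:
        sys_ = self._template
        try:
            sys_.set_parameters(x[:self.n_eps], self._c0_vector(x))
            init = np.ones(len(sys_.balanced_ids))
            for sid in self.model.extracellular_ids:
                c_post = self.design.post_perturbation_extracellular[sid]
                i = sys_.balanced_ids.index(sid)
                init[i] = max(c_post / sys_.c0[i], sys_.clamp)
            traj = sys_.simulate(init, self._times,
                                 rtol=self.options.sim_rtol,
                                 atol=self.options.sim_rtol * 1e-2)
            resid = (traj.values[self._obs_t, self._obs_s]
                     - self._obs_val) * self._obs_w
            chi2 = float(resid @ resid)
            if not np.isfinite(chi2):
                raise FloatingPointError("non-finite objective")
            return chi2
        except (RuntimeError, ValueError, FloatingPointError,
                np.linalg.LinAlgError):
            self.failures += 1
            return FAILURE_PENALTY


def _es_run(problem: _Problem, x_start: np.ndarray, budget: int,
            options: FitOptions, rng: np.random.Generator,
            trace: list[float]) -> tuple[np.ndarray, float, int]:
    """One (mu, lambda)-ES cycle with log-normal step-size self-adaptation."""
    n = problem.n
    tau = 1.0 / np.sqrt(2.0 * n)
    tau_p = 1.0 / np.sqrt(2.0 * np.sqrt(n))
    mu, lam = options.mu, options.lam

    # seed population around the start point
    pop_x = np.tile(x_start, (mu, 1))
    pop_s = np.full((mu, n), options.sigma_init)
    pop_f = np.empty(mu)
    evals = 0
    for i in range(mu):
        if i > 0:
            pop_x[i] = np.clip(
                x_start + options.sigma_init * rng.standard_normal(n),
                problem.lower, problem.upper)
        pop_f[i] = problem.objective(pop_x[i])
        evals += 1
    best_idx = int(np.argmin(pop_f))
    best_x, best_f = pop_x[best_idx].copy(), float(pop_f[best_idx])
    trace.append(best_f)

    while evals + lam <= budget:
        off_x = np.empty((lam, n))
        off_s = np.empty((lam, n))
        off_f = np.empty(lam)
        for k in range(lam):
            a, b = rng.integers(0, mu, size=2)
            x = 0.5 * (pop_x[a] + pop_x[b])          # intermediate recomb.
            s = np.sqrt(pop_s[a] * pop_s[b])
            g = tau * rng.standard_normal()
            s = s * np.exp(g + tau_p * rng.standard_normal(n))
            s = np.clip(s, 1e-10, 2.0)
            x = np.clip(x + s * rng.standard_normal(n),
                        problem.lower, problem.upper)
            off_x[k], off_s[k] = x, s
            off_f[k] = problem.objective(x)
        evals += lam
        order = np.argsort(off_f)[:mu]               # comma selection
        pop_x, pop_s, pop_f = off_x[order], off_s[order], off_f[order]
        if pop_f[0] < best_f:
            best_f = float(pop_f[0])
            best_x = pop_x[0].copy()
        trace.append(best_f)
    return best_x, best_f, evals


def fit(model: NetworkModel, data: MeasurementSet,
        design: PerturbationDesign, J0: dict[str, float],
        options: FitOptions | None = None, seed: int = 0,
        start_from: Parameterization | None = None) -> FitResult:
    """Fit elasticities (and free reference levels) to time-series data.

    Deterministic for a given seed.  ``options.multi_start`` independent
    starts are run on split budgets and the best result is returned.
    ``start_from`` overrides the default all-zero elasticity start point.
    """
    options = options or FitOptions()
    problem = _Problem(model, data, design, J0, options)
    master = np.random.default_rng(seed)
    k = max(1, options.multi_start)
    budgets = [options.budget // k] * k
    results = []
    total_evals = 0
    x0 = (problem.initial_guess() if start_from is None
          else problem.encode(start_from))
    for start in range(k):
        rng = np.random.default_rng(master.integers(0, 2**63 - 1))
        trace: list[float] = []
        x = x0.copy()
        if start > 0:
            x = np.clip(x + 0.5 * rng.standard_normal(problem.n),
                        problem.lower, problem.upper)
        remaining = budgets[start]
        restarts = 0
        best_x, best_f = x, np.inf
        while remaining > 0:
            cycle = min(remaining, options.restart_every)
            bx, bf, used = _es_run(problem, best_x, cycle, options, rng,
                                   trace)
            remaining -= used
            if used == 0:
                break
            if bf < best_f:
                best_x, best_f = bx, bf
            if remaining > 0:
                restarts += 1
        total_evals += budgets[start] - max(remaining, 0)
        results.append((best_f, best_x, trace, restarts))
    best_f, best_x, trace, restarts = min(results, key=lambda t: t[0])
    p = problem.decode(best_x)
    if problem.failures and best_f >= FAILURE_PENALTY:
        raise RuntimeError(
            f"all candidate simulations failed ({problem.failures} failures)")
    # recompute from scratch for the objective-equivalence contract
    chi2 = problem.objective(best_x)
    return FitResult(parameterization=p, chi2=chi2, evaluations=total_evals,
                     restarts=restarts, seed=seed, trace=trace)
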