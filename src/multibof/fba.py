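"""Linear-programming core: FBA, environment application, lexicographic
secretion maximization, parsimonious minimization, and the respiratory
quotient.

The LP backend is SciPy's HiGHS interface.  Feasibility and optimality
tolerances default to 1e-9 and can be overridden per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_io import MetabolicModel, Reaction

__all__ = [
    "FluxSolution",
    "EnvironmentPoint",
    "UndefinedRQError",
    "apply_environment",
    "solve_fba",
    "max_secretion_at_optimal_growth",
    "pfba_minimize",
    "respiratory_quotient",
    "DEFAULT_TOLERANCE",
    "FIXING_SLACK",
]

DEFAULT_TOLERANCE = 1e-9
#: Relative slack used when pinning a flux at a previously computed optimum.
FIXING_SLACK = 1e-9

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class UndefinedRQError(ArithmeticError):
    """Raised when RQ is requested but the solution takes up no oxygen."""


@dataclass
class FluxSolution:
    fluxes: dict[str, float]
    objective_value: float
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class EnvironmentPoint:
    """Nonnegative uptake magnitudes on named exchange reactions.

    mode "fixed" pins the exchange flux to -magnitude; mode "upper_bound"
    allows any uptake up to the magnitude.
    """

    uptakes: dict[str, float] = field(default_factory=dict)
    mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "upper_bound"):
            raise ValueError(f"unknown environment mode {self.mode!r}")
        bad = {k: v for k, v in self.uptakes.items() if v < 0}
        if bad:
            raise ValueError(f"negative uptake magnitudes: {bad}")

    def coordinates(self, dimensions: list[str]) -> np.ndarray:
        return np.array([self.uptakes[d] for d in dimensions], dtype=float)


def apply_environment(
    model: MetabolicModel,
    env: EnvironmentPoint,
    unconstrained_value: float = 1000.0,
) -> MetabolicModel:
    """Return a copy of *model* with the environment's uptake bounds applied.

    Exchanges named in the environment get fixed or upper-bounded uptake per
    the environment's mode.  All other exchanges that permit uptake in the
    base model are opened to the unconstrained value; secretion-only
    exchanges stay secretion-only.  Secretion is never constrained.
    """
    out = model.copy()
    for rid in env.uptakes:
        if not out.has_reaction(rid):
            raise KeyError(f"environment names unknown reaction {rid!r}")
        if not out.reaction(rid).is_exchange:
            raise ValueError(f"environment reaction {rid!r} is not an exchange")
    for rxn in out.exchanges():
        if rxn.id in env.uptakes:
            magnitude = env.uptakes[rxn.id]
            if env.mode == "fixed":
                rxn.lower_bound = -magnitude
                rxn.upper_bound = -magnitude
            else:
                rxn.lower_bound = -magnitude
                rxn.upper_bound = max(rxn.upper_bound, unconstrained_value)
        elif rxn.lower_bound < 0:
            rxn.lower_bound = -unconstrained_value
            rxn.upper_bound = max(rxn.upper_bound, unconstrained_value)
    return out


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def _stoichiometric_matrix(model: MetabolicModel):
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        for cid, coef in rxn.stoichiometry.items():
            rows.append(met_index[cid])
            cols.append(j)
            vals.append(coef)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


def _linprog(model: MetabolicModel, c: np.ndarray, sense: str, tolerance: float):
    """Solve min/max c.v s.t. S v = 0, bounds.  Returns (status, x, objective)."""
    S = _stoichiometric_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": tolerance,
            "dual_feasibility_tolerance": tolerance,
        },
    )
    if res.status == 0:
        return OPTIMAL, res.x, sign * res.fun
    if res.status == 2:
        return INFEASIBLE, None, float("nan")
    if res.status == 3:
        return UNBOUNDED, None, float("nan")
    raise RuntimeError(f"LP solver failure: {res.message}")


def solve_fba(
    model: MetabolicModel,
    objective: Mapping[str, float] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> FluxSolution:
    """Maximize the linear objective subject to S v = 0 and flux bounds."""
    obj = dict(objective) if objective is not None else dict(model.objective)
    if not obj:
        raise ValueError("empty objective")
    rxn_ids = [r.id for r in model.reactions]
    unknown = set(obj) - set(rxn_ids)
    if unknown:
        raise KeyError(f"objective names unknown reactions: {sorted(unknown)}")
    c = np.zeros(len(rxn_ids))
    for rid, coef in obj.items():
        c[rxn_ids.index(rid)] = coef
    status, x, val = _linprog(model, c, "max", tolerance)
    if status != OPTIMAL:
        return FluxSolution(fluxes={}, objective_value=float("nan"), status=status)
    return FluxSolution(
        fluxes=dict(zip(rxn_ids, map(float, x))), objective_value=float(val), status=status
    )


def _fix_flux(rxn: Reaction, value: float, slack: float = FIXING_SLACK) -> None:
    width = abs(value) * slack + slack
    rxn.lower_bound = value - width
    rxn.upper_bound = value + width


def max_secretion_at_optimal_growth(
    model: MetabolicModel,
    growth_rxn: str,
    target_exchange: str,
    tolerance: float = DEFAULT_TOLERANCE,
) -> FluxSolution:
    """Lexicographic two-stage LP: maximize growth, pin it, then maximize the
    target exchange's secretion flux.  The returned objective value is the
    secretion flux."""
    growth = solve_fba(model, {growth_rxn: 1.0}, tolerance=tolerance)
    if not growth.optimal:
        return growth
    staged = model.copy()
    _fix_flux(staged.reaction(growth_rxn), growth.objective_value)
    return solve_fba(staged, {target_exchange: 1.0}, tolerance=tolerance)


def pfba_minimize(
    model: MetabolicModel,
    fixed: Mapping[str, float] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> FluxSolution:
    """Minimize total absolute flux on the irreversible split of the network,
    holding the *fixed* reaction values (within the fixing slack)."""
    work = model.copy()
    for rid, value in (fixed or {}).items():
        _fix_flux(work.reaction(rid), value)
    # irreversible split: v = v+ - v-, both >= 0
    n = len(work.reactions)
    S = _stoichiometric_matrix(work)
    S2 = sparse.hstack([S, -S]).tocsr()
    bounds = []
    for r in work.reactions:
        bounds.append((max(r.lower_bound, 0.0), max(r.upper_bound, 0.0)))
    for r in work.reactions:
        bounds.append((max(-r.upper_bound, 0.0), max(-r.lower_bound, 0.0)))
    c = np.ones(2 * n)
    res = linprog(
        c,
        A_eq=S2,
        b_eq=np.zeros(S2.shape[0]),
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": tolerance,
            "dual_feasibility_tolerance": tolerance,
        },
    )
    if res.status == 2:
        return FluxSolution(fluxes={}, objective_value=float("nan"), status=INFEASIBLE)
    if res.status != 0:
        return FluxSolution(fluxes={}, objective_value=float("nan"), status=UNBOUNDED)
    v = res.x[:n] - res.x[n:]
    rxn_ids = [r.id for r in work.reactions]
    return FluxSolution(
        fluxes=dict(zip(rxn_ids, map(float, v))),
        objective_value=float(res.fun),
        status=OPTIMAL,
    )


def total_absolute_flux(solution: FluxSolution) -> float:
    return sum(abs(v) for v in solution.fluxes.values())


def respiratory_quotient(
    model: MetabolicModel,
    env: EnvironmentPoint,
    bof_rxn: str,
    acetate_rxn: str = "EX_ac_e",
    o2_rxn: str = "EX_o2_e",
    co2_rxn: str = "EX_co2_e",
    tolerance: float = DEFAULT_TOLERANCE,
) -> float:
    """Three-level RQ determination.

    Maximize growth; pin it; maximize acetate secretion; pin it; minimize
    total absolute flux parsimoniously.  RQ is the CO2 secretion flux over
    the O2 uptake magnitude of the final solution.
    """
    conditioned = apply_environment(model, env)
    growth = solve_fba(conditioned, {bof_rxn: 1.0}, tolerance=tolerance)
    if not growth.optimal:
        raise RuntimeError(f"growth stage not optimal: {growth.status}")
    staged = conditioned.copy()
    _fix_flux(staged.reaction(bof_rxn), growth.objective_value)
    acetate = solve_fba(staged, {acetate_rxn: 1.0}, tolerance=tolerance)
    if not acetate.optimal:
        raise RuntimeError(f"acetate stage not optimal: {acetate.status}")
    parsimonious = pfba_minimize(
        conditioned,
        fixed={bof_rxn: growth.objective_value, acetate_rxn: acetate.objective_value},
        tolerance=tolerance,
    )
    if not parsimonious.optimal:
        raise RuntimeError(f"parsimonious stage not optimal: {parsimonious.status}")
    o2_uptake = -parsimonious.fluxes[o2_rxn]
    co2_out = parsimonious.fluxes[co2_rxn]
    if o2_uptake <= max(tolerance * 1e3, 1e-12):
        raise UndefinedRQError(
            f"oxygen uptake is {o2_uptake:.3e}; respiratory quotient undefined"
        )
    return co2_out / o2_uptake
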