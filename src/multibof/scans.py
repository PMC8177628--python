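"""Phenotype phase-plane scans over two uptake axes (growth, maximal acetate
secretion, respiratory quotient) for any biomass source, plus relative grids."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bof import BiomassComposition, bof_to_reaction
from .fba import (
    DEFAULT_TOLERANCE,
    EnvironmentPoint,
    UndefinedRQError,
    apply_environment,
    max_secretion_at_optimal_growth,
    respiratory_quotient,
    solve_fba,
)
from .methods import (
    AffineBofMap,
    BTW_PREFIX,
    HIP_REACTION,
    build_btw,
    hip_bof,
    hip_i_solve,
    solve_btw,
)
from .model_io import MetabolicModel

__all__ = [
    "Axis",
    "Cell",
    "PhasePlaneGrid",
    "FixedBofSource",
    "BtwSource",
    "HipSource",
    "HipISource",
    "scan_phase_plane",
    "relative_grid",
    "STATUS_OK",
    "STATUS_NO_GROWTH",
    "STATUS_INFEASIBLE",
    "STATUS_UNDEFINED_POSITIVE",
    "STATUS_ZERO_ZERO",
]

STATUS_OK = "ok"
STATUS_NO_GROWTH = "no_growth"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNDEFINED_POSITIVE = "undefined_positive"
STATUS_ZERO_ZERO = "zero_zero"

GROWTH_EPS = 1e-9


@dataclass(frozen=True)
class Axis:
    exchange_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError(f"axis {self.exchange_id} has no values")
        if any(v < 0 for v in self.values):
            raise ValueError(f"axis {self.exchange_id} has negative uptake values")


@dataclass
class Cell:
    growth: float = float("nan")
    acetate: float = float("nan")
    rq: float = float("nan")
    status: str = STATUS_OK


@dataclass
class PhasePlaneGrid:
    c_axis: Axis
    n_axis: Axis
    cells: dict[tuple[int, int], Cell]
    bof_source: str = ""
    mode: str = "fixed"

    def cell(self, i: int, j: int) -> Cell:
        return self.cells[(i, j)]

    def array(self, phenotype: str) -> np.ndarray:
        out = np.full((len(self.c_axis.values), len(self.n_axis.values)), np.nan)
        for (i, j), cell in self.cells.items():
            out[i, j] = getattr(cell, phenotype)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, j), cell in sorted(self.cells.items()):
            rows.append(
                {
                    self.c_axis.exchange_id: self.c_axis.values[i],
                    self.n_axis.exchange_id: self.n_axis.values[j],
                    "growth": cell.growth,
                    "acetate": cell.acetate,
                    "rq": cell.rq,
                    "status": cell.status,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Biomass sources
# ---------------------------------------------------------------------------

@dataclass
class FixedBofSource:
    """A single, environment-independent biomass reaction already in the model
    (a reaction id) or a composition to attach."""

    bof: str | BiomassComposition
    tag: str = "fixed"

    def prepare(self, model: MetabolicModel) -> tuple[MetabolicModel, str]:
        if isinstance(self.bof, str):
            if not model.has_reaction(self.bof):
                raise KeyError(f"model has no biomass reaction {self.bof!r}")
            return model, self.bof
        work = model.copy()
        rid = "BIOMASS_FIXED"
        work.add_reaction(bof_to_reaction(self.bof, rid))
        return work, rid


@dataclass
class BtwSource:
    bofs: Sequence[BiomassComposition]
    tag: str = "btw"


@dataclass
class HipSource:
    map: AffineBofMap
    tag: str = "hip"


@dataclass
class HipISource:
    map: AffineBofMap
    eps: float = 1e-3
    k_max: int = 100
    tag: str = "hipi"


BofSource = FixedBofSource | BtwSource | HipSource | HipISource


def _evaluate_fixed(
    model: MetabolicModel,
    growth_rxn: str,
    env: EnvironmentPoint,
    phenotypes: Sequence[str],
    acetate_rxn: str,
    o2_rxn: str,
    co2_rxn: str,
    tolerance: float,
) -> Cell:
    cell = Cell()
    conditioned = apply_environment(model, env)
    sol = solve_fba(conditioned, {growth_rxn: 1.0}, tolerance=tolerance)
    if not sol.optimal:
        cell.status = STATUS_INFEASIBLE
        return cell
    cell.growth = sol.objective_value
    if cell.growth <= GROWTH_EPS:
        cell.status = STATUS_NO_GROWTH
        return cell
    if "acetate" in phenotypes:
        ac = max_secretion_at_optimal_growth(
            conditioned, growth_rxn, acetate_rxn, tolerance=tolerance
        )
        cell.acetate = ac.objective_value if ac.optimal else float("nan")
    if "rq" in phenotypes:
        try:
            cell.rq = respiratory_quotient(
                model, env, growth_rxn, acetate_rxn, o2_rxn, co2_rxn, tolerance=tolerance
            )
        except (UndefinedRQError, RuntimeError):
            cell.rq = float("nan")
    return cell


def scan_phase_plane(
    model: MetabolicModel,
    bof_source: BofSource,
    c_values: Sequence[float],
    n_values: Sequence[float],
    phenotypes: Sequence[str] = ("growth", "acetate", "rq"),
    mode: str = "fixed",
    c_exchange: str = "EX_glc__D_e",
    n_exchange: str = "EX_nh4_e",
    acetate_rxn: str = "EX_ac_e",
    o2_rxn: str = "EX_o2_e",
    co2_rxn: str = "EX_co2_e",
    tolerance: float = DEFAULT_TOLERANCE,
) -> PhasePlaneGrid:
    """Evaluate the requested phenotypes on every (carbon, nitrogen) uptake
    coordinate; cells are computed independently and failures are recorded in
    each cell's status rather than raised."""
    c_axis = Axis(c_exchange, tuple(float(v) for v in c_values))
    n_axis = Axis(n_exchange, tuple(float(v) for v in n_values))
    if isinstance(bof_source, HipISource) and mode != "upper_bound":
        raise ValueError("HIP-I scans require upper_bound mode")
    cells: dict[tuple[int, int], Cell] = {}
    prepared: MetabolicModel | None = None
    growth_rxn = ""
    if isinstance(bof_source, FixedBofSource):
        prepared, growth_rxn = bof_source.prepare(model)
    elif isinstance(bof_source, BtwSource):
        prepared = build_btw(model, list(bof_source.bofs))
    for i, c in enumerate(c_axis.values):
        for j, n in enumerate(n_axis.values):
            env = EnvironmentPoint(
                uptakes={c_exchange: c, n_exchange: n}, mode=mode
            )
            if isinstance(bof_source, FixedBofSource):
                cell = _evaluate_fixed(
                    prepared, growth_rxn, env, phenotypes,
                    acetate_rxn, o2_rxn, co2_rxn, tolerance,
                )
            elif isinstance(bof_source, BtwSource):
                cell = Cell()
                sol = solve_btw(prepared, env, tolerance=tolerance)
                if not sol.optimal:
                    cell.status = STATUS_INFEASIBLE
                elif sol.objective_value <= GROWTH_EPS:
                    cell.status = STATUS_NO_GROWTH
                else:
                    cell.growth = sol.objective_value
                    if "acetate" in phenotypes:
                        staged = apply_environment(prepared, env)
                        for rid, v in sol.bof_fluxes.items():
                            rxn = staged.reaction(rid)
                            width = abs(v) * 1e-9 + 1e-9
                            rxn.lower_bound, rxn.upper_bound = v - width, v + width
                        ac = solve_fba(staged, {acetate_rxn: 1.0}, tolerance=tolerance)
                        cell.acetate = ac.objective_value if ac.optimal else float("nan")
            elif isinstance(bof_source, HipSource):
                # a fresh BOF is generated for every coordinate
                bof = hip_bof(bof_source.map, env)
                fixed = FixedBofSource(bof, tag="hip")
                work, rid = fixed.prepare(model)
                cell = _evaluate_fixed(
                    work, rid, env, phenotypes,
                    acetate_rxn, o2_rxn, co2_rxn, tolerance,
                )
            elif isinstance(bof_source, HipISource):
                cell = Cell()
                result = hip_i_solve(
                    model, bof_source.map, env,
                    eps=bof_source.eps, k_max=bof_source.k_max, tolerance=tolerance,
                )
                if result.solution is None or not result.solution.optimal:
                    cell.status = STATUS_INFEASIBLE
                elif not result.converged:
                    cell.status = "unstable"
                else:
                    cell.growth = result.solution.objective_value
                    if cell.growth <= GROWTH_EPS:
                        cell.status = STATUS_NO_GROWTH
            else:
                raise TypeError(f"unknown biomass source {type(bof_source).__name__}")
            cells[(i, j)] = cell
    return PhasePlaneGrid(
        c_axis=c_axis, n_axis=n_axis, cells=cells,
        bof_source=bof_source.tag, mode=mode,
    )


def relative_grid(
    grid: PhasePlaneGrid,
    reference_grid: PhasePlaneGrid,
    cap: float = 10.0,
) -> PhasePlaneGrid:
    """Cell-wise ratio grid (grid / reference).

    0/0 is reported as 1 with a ``zero_zero`` status; a positive numerator
    over a zero reference is flagged ``undefined_positive``.  Acetate ratios
    are capped at *cap* because tiny reference secretions blow up the ratio.
    """
    if (grid.c_axis, grid.n_axis) != (reference_grid.c_axis, reference_grid.n_axis):
        raise ValueError("grids have different axes")
    cells: dict[tuple[int, int], Cell] = {}
    for key, cell in grid.cells.items():
        ref = reference_grid.cells[key]
        out = Cell(status=cell.status)
        if STATUS_INFEASIBLE in (cell.status, ref.status):
            out.status = STATUS_INFEASIBLE
            cells[key] = out
            continue
        for phenotype, apply_cap in (("growth", False), ("acetate", True), ("rq", False)):
            num = getattr(cell, phenotype)
            den = getattr(ref, phenotype)
            if np.isnan(num) or np.isnan(den):
                continue
            if den == 0.0:
                if num == 0.0:
                    setattr(out, phenotype, 1.0)
                    if out.status == STATUS_OK:
                        out.status = STATUS_ZERO_ZERO
                else:
                    if out.status == STATUS_OK:
                        out.status = STATUS_UNDEFINED_POSITIVE
                continue
            ratio = num / den
            if apply_cap and ratio > cap:
                ratio = cap
            setattr(out, phenotype, ratio)
        cells[key] = out
    return PhasePlaneGrid(
        c_axis=grid.c_axis,
        n_axis=grid.n_axis,
        cells=cells,
        bof_source=f"{grid.bof_source}/{reference_grid.bof_source}",
        mode=grid.mode,
    )
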