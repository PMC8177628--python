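"""Single-gene knockout screens via GPR evaluation, growth-ratio binning,
three-group tallies, and the angle-based similarity score against
experimental essentiality tables."""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fba import DEFAULT_TOLERANCE, EnvironmentPoint, apply_environment, solve_fba
from .methods import AffineBofMap, build_btw, hip_i_solve, hip_solve, solve_btw
from .model_io import MetabolicModel

__all__ = [
    "KnockoutTable",
    "GrowthBins",
    "GroupVector",
    "GprError",
    "evaluate_gpr",
    "single_gene_deletion",
    "bin_ratios",
    "three_group_vector",
    "experimental_groups",
    "similarity_angle",
    "ESSENTIALITY_THRESHOLD",
    "BIN_EDGES",
]

#: grRatio below this value marks a gene essential (growth reduced >= 99%).
ESSENTIALITY_THRESHOLD = 1e-2

#: Growth-ratio histogram intervals:
#: [0, 0.01) / [0.01, 0.50] / (0.50, 0.88] / (0.88, 0.98] / (0.98, 1]
BIN_EDGES = (0.01, 0.50, 0.88, 0.98)

RATIO_CLIP_TOL = 1e-6


class GprError(ValueError):
    """Raised for malformed gene-protein-reaction rules."""


# ---------------------------------------------------------------------------
# GPR evaluation
# ---------------------------------------------------------------------------

def _eval_node(node: ast.AST, active: Mapping[str, bool]) -> bool:
    if isinstance(node, ast.BoolOp):
        values = [_eval_node(v, active) for v in node.values]
        return all(values) if isinstance(node.op, ast.And) else any(values)
    if isinstance(node, ast.Name):
        return active.get(node.id, True)
    raise GprError(f"unsupported GPR element: {ast.dump(node)}")


def evaluate_gpr(rule: str, knocked: str | Iterable[str]) -> bool:
    """Evaluate a boolean GPR with the knocked gene(s) set to false and all
    others true.  An empty rule means the reaction is always active."""
    if not rule or not rule.strip():
        return True
    knocked_set = {knocked} if isinstance(knocked, str) else set(knocked)
    normalized = rule.replace(" AND ", " and ").replace(" OR ", " or ")
    try:
        tree = ast.parse(normalized, mode="eval")
    except SyntaxError as exc:
        raise GprError(f"malformed GPR {rule!r}: {exc}") from exc
    return _eval_node(tree.body, {g: False for g in knocked_set})


# ---------------------------------------------------------------------------
# Knockout screen
# ---------------------------------------------------------------------------

@dataclass
class KnockoutTable:
    ratios: dict[str, float]
    method: str
    environment: EnvironmentPoint

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "grRatio": r,
                "essential": r < ESSENTIALITY_THRESHOLD,
            }
            for g, r in sorted(self.ratios.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "grRatio", "essential"])

    def essential_genes(self) -> list[str]:
        return sorted(g for g, r in self.ratios.items() if r < ESSENTIALITY_THRESHOLD)


def _knockout_model(model: MetabolicModel, gene: str) -> MetabolicModel:
    mutant = model.copy()
    for rxn in mutant.reactions:
        if rxn.gpr and not evaluate_gpr(rxn.gpr, gene):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return mutant


def _growth(
    model: MetabolicModel,
    env: EnvironmentPoint,
    method: str,
    bof_rxn: str | None,
    map: AffineBofMap | None,
    bofs,
    eps: float,
    k_max: int,
    tolerance: float,
) -> float:
    """Optimal growth of *model* at *env* under the named method; infeasible
    or unconverged solves count as zero growth."""
    if method == "fixed":
        sol = solve_fba(
            apply_environment(model, env), {bof_rxn: 1.0}, tolerance=tolerance
        )
        return sol.objective_value if sol.optimal else 0.0
    if method == "btw":
        sol = solve_btw(build_btw(model, bofs), env, tolerance=tolerance)
        return sol.objective_value if sol.optimal else 0.0
    if method == "hip":
        sol = hip_solve(model, map, env, tolerance=tolerance)
        return sol.objective_value if sol.optimal else 0.0
    if method == "hipi":
        result = hip_i_solve(model, map, env, eps=eps, k_max=k_max, tolerance=tolerance)
        if result.solution is None or not result.solution.optimal:
            return 0.0
        if not result.converged:
            return 0.0
        return result.solution.objective_value
    raise ValueError(f"unknown knockout method {method!r}")


def single_gene_deletion(
    model: MetabolicModel,
    env: EnvironmentPoint,
    method: str = "fixed",
    bof_rxn: str | None = None,
    map: AffineBofMap | None = None,
    bofs=None,
    eps: float = 1e-3,
    k_max: int = 100,
    tolerance: float = DEFAULT_TOLERANCE,
) -> KnockoutTable:
    """Knock out each gene in turn (GPR-inactive reactions bounded to zero)
    and re-optimize growth under the SAME method as the wild type; HIP-I
    mutants re-iterate from the wild-type starting bounds."""
    wt = _growth(model, env, method, bof_rxn, map, bofs, eps, k_max, tolerance)
    if wt <= 0.0:
        raise ValueError("wild-type growth is zero at this environment")
    ratios: dict[str, float] = {}
    for gene in model.genes:
        mutant = _knockout_model(model, gene)
        changed = any(
            m.lower_bound != o.lower_bound or m.upper_bound != o.upper_bound
            for m, o in zip(mutant.reactions, model.reactions)
        )
        if not changed:
            ratios[gene] = 1.0
            continue
        growth = _growth(mutant, env, method, bof_rxn, map, bofs, eps, k_max, tolerance)
        ratio = max(growth, 0.0) / wt
        if ratio > 1.0 and ratio <= 1.0 + RATIO_CLIP_TOL:
            ratio = 1.0
        ratios[gene] = ratio
    return KnockoutTable(ratios=ratios, method=method, environment=env)


# ---------------------------------------------------------------------------
# Binning and similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthBins:
    counts: tuple[int, int, int, int, int]

    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class GroupVector:
    essential: int
    intermediate: int
    no_effect: int

    def as_array(self) -> np.ndarray:
        return np.array([self.essential, self.intermediate, self.no_effect], float)

    def total(self) -> int:
        return self.essential + self.intermediate + self.no_effect


def _clip_ratio(r: float) -> float:
    if r < 0.0:
        return 0.0
    return min(r, 1.0)


def bin_ratios(table: KnockoutTable | Mapping[str, float]) -> GrowthBins:
    """Histogram growth ratios into
    [0, 0.01) / [0.01, 0.50] / (0.50, 0.88] / (0.88, 0.98] / (0.98, 1]."""
    ratios = table.ratios if isinstance(table, KnockoutTable) else table
    counts = [0, 0, 0, 0, 0]
    e1, e2, e3, e4 = BIN_EDGES
    for r in ratios.values():
        r = _clip_ratio(r)
        if r < e1:
            counts[0] += 1
        elif r <= e2:
            counts[1] += 1
        elif r <= e3:
            counts[2] += 1
        elif r <= e4:
            counts[3] += 1
        else:
            counts[4] += 1
    return GrowthBins(counts=tuple(counts))


def three_group_vector(table: KnockoutTable | Mapping[str, float]) -> GroupVector:
    """Coarsen ratios into (essential, intermediate, no-effect) fitness
    classes [0, 0.01) / [0.01, 0.98] / (0.98, 1]."""
    ratios = table.ratios if isinstance(table, KnockoutTable) else table
    essential = intermediate = no_effect = 0
    for r in ratios.values():
        r = _clip_ratio(r)
        if r < ESSENTIALITY_THRESHOLD:
            essential += 1
        elif r <= 0.98:
            intermediate += 1
        else:
            no_effect += 1
    return GroupVector(essential, intermediate, no_effect)


def experimental_groups(scores: Mapping[str, float] | Sequence[float]) -> GroupVector:
    """Tally experimental knockout scores: s < -3 essential, -3 <= s < -1
    intermediate, s >= -1 no effect."""
    values = scores.values() if isinstance(scores, Mapping) else scores
    essential = intermediate = no_effect = 0
    for s in values:
        if s < -3:
            essential += 1
        elif s < -1:
            intermediate += 1
        else:
            no_effect += 1
    return GroupVector(essential, intermediate, no_effect)


def similarity_angle(
    u: GroupVector | Sequence[float], v: GroupVector | Sequence[float]
) -> float:
    """Angle theta = acos(u.v / (|u| |v|)) between two tally vectors, in
    radians; zero for perfectly aligned tallies."""
    ua = u.as_array() if isinstance(u, GroupVector) else np.asarray(u, float)
    va = v.as_array() if isinstance(v, GroupVector) else np.asarray(v, float)
    nu, nv = np.linalg.norm(ua), np.linalg.norm(va)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("similarity_angle is undefined for a zero vector")
    cosine = float(np.dot(ua, va) / (nu * nv))
    return float(np.arccos(np.clip(cosine, -1.0, 1.0)))
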