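"""Multi-biomass analysis methods: biomass tradeoff weighting (BTW),
higher-dimensional-plane interpolation (HIP), and its iterative,
self-consistent extension (HIP-I)."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bof import (
    BiomassComposition,
    BofEntry,
    CONSUMED,
    bof_to_reaction,
    normalize_unit_mass,
)
from .fba import (
    DEFAULT_TOLERANCE,
    EnvironmentPoint,
    FluxSolution,
    apply_environment,
    solve_fba,
)
from .model_io import MetabolicModel

__all__ = [
    "BOFMeasurement",
    "MeasurementSet",
    "AffineBofMap",
    "BtwSolution",
    "HipIResult",
    "build_btw",
    "solve_btw",
    "fit_affine_map",
    "hip_bof",
    "hip_solve",
    "hip_i_solve",
    "BTW_PREFIX",
    "HIP_REACTION",
]

BTW_PREFIX = "BTW_BIOMASS_"
HIP_REACTION = "BIOMASS_HIP"

MASS_TOL = 1e-9


# ---------------------------------------------------------------------------
# BTW
# ---------------------------------------------------------------------------

@dataclass
class BtwSolution(FluxSolution):
    """FBA solution with the per-BOF split of the combined objective."""

    bof_fluxes: dict[str, float] = field(default_factory=dict)


def build_btw(
    model: MetabolicModel, bofs: Sequence[BiomassComposition]
) -> MetabolicModel:
    """Attach every composition as an irreversible pseudo-reaction and set the
    objective coefficient of each to one (all other entries zero)."""
    if not bofs:
        raise ValueError("build_btw requires at least one biomass composition")
    out = model.copy()
    met_ids = {m.id for m in out.metabolites}
    objective: dict[str, float] = {}
    for i, bof in enumerate(bofs):
        missing = sorted(set(bof.entries) - met_ids)
        if missing:
            raise KeyError(
                f"BOF {bof.label or i!r} compounds absent from model: {missing}"
            )
        rid = BTW_PREFIX + (bof.label or str(i))
        out.add_reaction(bof_to_reaction(bof, rid))
        objective[rid] = 1.0
    out.objective = objective
    return out


def solve_btw(
    model: MetabolicModel,
    env: EnvironmentPoint | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> BtwSolution:
    """Solve the BTW LP; the objective value is the summed flux over all
    attached BOF reactions, reported individually in ``bof_fluxes``."""
    bof_ids = [r.id for r in model.reactions if r.id.startswith(BTW_PREFIX)]
    if not bof_ids:
        raise ValueError("model has no BTW biomass reactions; call build_btw first")
    work = apply_environment(model, env) if env is not None else model
    sol = solve_fba(work, {rid: 1.0 for rid in bof_ids}, tolerance=tolerance)
    split = {rid: sol.fluxes.get(rid, float("nan")) for rid in bof_ids}
    return BtwSolution(
        fluxes=sol.fluxes,
        objective_value=sol.objective_value,
        status=sol.status,
        bof_fluxes=split,
    )


# ---------------------------------------------------------------------------
# HIP
# ---------------------------------------------------------------------------

@dataclass
class BOFMeasurement:
    environment: EnvironmentPoint
    composition: BiomassComposition


@dataclass
class MeasurementSet:
    measurements: list[BOFMeasurement]
    dimensions: list[str]

    def coordinates(self) -> np.ndarray:
        return np.array(
            [m.environment.coordinates(self.dimensions) for m in self.measurements]
        )

    def compound_universe(self) -> list[str]:
        universe: set[str] = set()
        for m in self.measurements:
            universe |= set(m.composition.entries)
        return sorted(universe)


@dataclass
class AffineBofMap:
    """Per-compound affine map from n-dimensional uptake coordinates to BOF
    coefficients: alpha_i(x) = intercept_i + slopes_i . x."""

    dimensions: list[str]
    compounds: list[str]
    coefficients: np.ndarray  # shape (m, n+1): column 0 intercept, then slopes
    sides: dict[str, str]
    groups: dict[str, str]
    weights: dict[str, float | None]
    reference: BiomassComposition
    clamp_fraction: float = 0.01
    fit_mode: str = "exact"

    def raw_coefficients(self, coords: np.ndarray) -> np.ndarray:
        x = np.concatenate([[1.0], np.asarray(coords, dtype=float)])
        if x.shape[0] != self.coefficients.shape[1]:
            raise ValueError(
                f"environment has {x.shape[0] - 1} dimensions, map expects "
                f"{self.coefficients.shape[1] - 1}"
            )
        return self.coefficients @ x


def fit_affine_map(
    ms: MeasurementSet,
    reference: BiomassComposition,
    clamp_fraction: float = 0.01,
) -> AffineBofMap:
    """Fit one affine plane per compound through the measured compositions.

    Exactly n+1 affinely independent points give the unique interpolating
    plane; more points give the least-squares plane; fewer are an error.
    Compounds missing from a measurement contribute coefficient zero there.
    """
    n = len(ms.dimensions)
    k = len(ms.measurements)
    if k < n + 1:
        raise ValueError(
            f"need at least {n + 1} measurements for {n} dimensions, got {k}"
        )
    for m in ms.measurements:
        mass_err = _consumed_mass(m.composition) - 1.0
        if abs(mass_err) > 1e-6:
            raise ValueError(
                f"measurement {m.composition.label!r} is not unit-mass normalized "
                f"(deviation {mass_err:.2e})"
            )
    X = np.hstack([np.ones((k, 1)), ms.coordinates()])  # (k, n+1)
    compounds = ms.compound_universe()
    Y = np.zeros((k, len(compounds)))
    sides: dict[str, str] = {}
    groups: dict[str, str] = {}
    weights: dict[str, float | None] = {}
    for row, m in enumerate(ms.measurements):
        for col, cid in enumerate(compounds):
            entry = m.composition.entries.get(cid)
            if entry is None:
                continue
            Y[row, col] = entry.coefficient
            if cid in sides and sides[cid] != entry.side:
                raise ValueError(f"side conflict across measurements for {cid!r}")
            sides[cid] = entry.side
            groups[cid] = entry.group
            if entry.molecular_weight is not None:
                weights[cid] = entry.molecular_weight
    for cid in compounds:
        sides.setdefault(cid, CONSUMED)
        groups.setdefault(cid, "Others")
        weights.setdefault(cid, None)
    if k == n + 1:
        if np.linalg.matrix_rank(X) < n + 1:
            raise np.linalg.LinAlgError(
                "environment points are affinely dependent; exact interpolation "
                "is rank-deficient"
            )
        W = np.linalg.solve(X, Y).T  # (m, n+1)
        fit_mode = "exact"
    else:
        W = np.linalg.lstsq(X, Y, rcond=None)[0].T
        fit_mode = "least_squares"
    return AffineBofMap(
        dimensions=list(ms.dimensions),
        compounds=compounds,
        coefficients=W,
        sides=sides,
        groups=groups,
        weights=weights,
        reference=reference,
        clamp_fraction=clamp_fraction,
        fit_mode=fit_mode,
    )


def _consumed_mass(bof: BiomassComposition) -> float:
    return sum(
        e.coefficient * (e.molecular_weight or 0.0) / 1000.0
        for e in bof.consumed().values()
    )


def hip_bof(
    map: AffineBofMap,
    env: EnvironmentPoint | np.ndarray,
    renormalize: bool = True,
) -> BiomassComposition:
    """Evaluate the affine map at an environment coordinate.

    Raw negative coefficients are clamped to ``clamp_fraction`` times the
    reference (UL) coefficient — zero when the reference lacks the compound —
    and the result is renormalized to unit consumed mass.
    """
    coords = (
        env.coordinates(map.dimensions)
        if isinstance(env, EnvironmentPoint)
        else np.asarray(env, dtype=float)
    )
    raw = map.raw_coefficients(coords)
    entries: dict[str, BofEntry] = {}
    for cid, value in zip(map.compounds, raw):
        if value < 0:
            ref_entry = map.reference.entries.get(cid)
            value = (
                map.clamp_fraction * ref_entry.coefficient
                if ref_entry is not None
                else 0.0
            )
        if value == 0.0:
            continue
        entries[cid] = BofEntry(
            coefficient=float(value),
            side=map.sides[cid],
            group=map.groups[cid],
            molecular_weight=map.weights[cid],
        )
    label = "HIP(" + ",".join(f"{c:g}" for c in coords) + ")"
    bof = BiomassComposition(entries=entries, label=label)
    return normalize_unit_mass(bof) if renormalize else bof


def _attach_hip_bof(model: MetabolicModel, bof: BiomassComposition) -> MetabolicModel:
    out = model.copy()
    if out.has_reaction(HIP_REACTION):
        out.reactions = [r for r in out.reactions if r.id != HIP_REACTION]
        out._reindex()
    out.add_reaction(bof_to_reaction(bof, HIP_REACTION))
    out.objective = {HIP_REACTION: 1.0}
    return out


def hip_solve(
    model: MetabolicModel,
    map: AffineBofMap,
    env: EnvironmentPoint,
    tolerance: float = DEFAULT_TOLERANCE,
) -> FluxSolution:
    """Generate the environment's BOF with the map, attach it, and solve FBA
    with the environment applied in its stated mode."""
    bof = hip_bof(map, env)
    work = apply_environment(_attach_hip_bof(model, bof), env)
    return solve_fba(work, {HIP_REACTION: 1.0}, tolerance=tolerance)


# ---------------------------------------------------------------------------
# HIP-I
# ---------------------------------------------------------------------------

@dataclass
class HipIResult:
    start: EnvironmentPoint
    trajectory: list[np.ndarray]      # uptake vectors v_1 .. v_k (+ final test vector)
    compositions: list[BiomassComposition]  # B_0 .. B_k
    converged: bool
    iterations: int
    epsilon: float
    k_max: int
    solution: FluxSolution | None = None

    @property
    def final_uptakes(self) -> np.ndarray | None:
        return self.trajectory[-1] if self.trajectory else None


def _uptake_vector(sol: FluxSolution, dimensions: list[str]) -> np.ndarray:
    return np.array([max(0.0, -sol.fluxes[d]) for d in dimensions])


def hip_i_solve(
    model: MetabolicModel,
    map: AffineBofMap,
    u: EnvironmentPoint,
    eps: float = 1e-3,
    k_max: int = 100,
    tolerance: float = DEFAULT_TOLERANCE,
    deterministic_uptake: bool = False,
) -> HipIResult:
    """Iterate HIP until the FBA-optimal uptake vector is self-consistent.

    The starting coordinates u (upper bounds) generate B_0; each FBA solve is
    constrained by the ORIGINAL upper bounds while the BOF is re-queried at
    the realized uptakes v_k.  Convergence is the infinity norm of
    (v_k - v_{k-1}) over the map's dimensions falling to eps or below, with
    v_0 compared against u itself.  With ``deterministic_uptake`` the realized
    uptakes come from a secondary stage minimizing total uptake magnitude at
    fixed optimal growth, removing alternate-optimum ambiguity.
    """
    if u.mode != "upper_bound":
        raise ValueError("HIP-I requires an upper_bound-mode environment")
    prev = u.coordinates(map.dimensions)
    bof = hip_bof(map, prev)
    compositions = [bof]
    trajectory: list[np.ndarray] = []
    solution: FluxSolution | None = None
    converged = False
    iterations = 0
    for k in range(k_max + 1):
        work = apply_environment(_attach_hip_bof(model, bof), u)
        sol = solve_fba(work, {HIP_REACTION: 1.0}, tolerance=tolerance)
        if not sol.optimal:
            return HipIResult(
                start=u,
                trajectory=trajectory,
                compositions=compositions,
                converged=False,
                iterations=k,
                epsilon=eps,
                k_max=k_max,
                solution=sol,
            )
        if deterministic_uptake:
            staged = work.copy()
            value = sol.objective_value
            width = abs(value) * 1e-9 + 1e-9
            rxn = staged.reaction(HIP_REACTION)
            rxn.lower_bound, rxn.upper_bound = value - width, value + width
            stage2 = solve_fba(
                staged, {d: 1.0 for d in map.dimensions}, tolerance=tolerance
            )
            if stage2.optimal:
                sol = FluxSolution(
                    fluxes=stage2.fluxes, objective_value=value, status=stage2.status
                )
        v = _uptake_vector(sol, map.dimensions)
        trajectory.append(v)
        solution = sol
        iterations = k
        if float(np.max(np.abs(v - prev))) <= eps:
            converged = True
            break
        if k == k_max:
            break
        prev = v
        bof = hip_bof(map, v)
        compositions.append(bof)
    return HipIResult(
        start=u,
        trajectory=trajectory,
        compositions=compositions,
        converged=converged,
        iterations=iterations,
        epsilon=eps,
        k_max=k_max,
        solution=solution,
    )
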