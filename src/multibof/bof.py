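"""Biomass objective function (BOF) construction, merging, scaling, and
mass normalization.

A BOF is stored as a composition table: one entry per compound carrying a
nonnegative coefficient (mmol per unit biomass flux), a side (consumed or
produced), a macromolecular group, and a molecular weight.  The consumed-side
mass of a valid production BOF is normalized to 1 g gCDW^-1 so that unit flux
through the pseudo-reaction drains exactly one gram of biomass precursors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .model_io import MetabolicModel, Reaction, metabolite_weight

__all__ = [
    "GROUPS",
    "BofEntry",
    "BiomassComposition",
    "ScalingTable",
    "limitation_scaling_table",
    "mean_bofs",
    "remove_compound",
    "bof_mass",
    "normalize_unit_mass",
    "scale_groups",
    "build_artificial_bofs",
    "bof_to_reaction",
    "read_bof_table",
    "write_bof_table",
]

#: The nine macromolecular groups used for environment-dependent scaling.
GROUPS = (
    "DNA",
    "RNA",
    "Protein",
    "Lipid",
    "Carbohydrates",
    "Energy",
    "Co-factors",
    "Ions",
    "Others",
)

CONSUMED = "consumed"
PRODUCED = "produced"


@dataclass(frozen=True)
class BofEntry:
    coefficient: float
    side: str = CONSUMED
    group: str = "Others"
    molecular_weight: float | None = None

    def __post_init__(self) -> None:
        if self.coefficient < 0:
            raise ValueError("BOF coefficients are stored nonnegative; side carries sign")
        if self.side not in (CONSUMED, PRODUCED):
            raise ValueError(f"unknown side {self.side!r}")


@dataclass
class BiomassComposition:
    """A biomass composition: compound id -> entry, plus a label."""

    entries: dict[str, BofEntry] = field(default_factory=dict)
    label: str = ""

    def consumed(self) -> dict[str, BofEntry]:
        return {k: e for k, e in self.entries.items() if e.side == CONSUMED}

    def produced(self) -> dict[str, BofEntry]:
        return {k: e for k, e in self.entries.items() if e.side == PRODUCED}

    def scaled(self, factor: float, label: str | None = None) -> "BiomassComposition":
        return BiomassComposition(
            entries={
                k: replace(e, coefficient=e.coefficient * factor)
                for k, e in self.entries.items()
            },
            label=self.label if label is None else label,
        )

    def group_mass(self, group: str) -> float:
        """Consumed-side gram contribution of one group per unit flux."""
        total = 0.0
        for e in self.consumed().values():
            if e.group == group:
                total += e.coefficient * _require_weight(e) / 1000.0
        return total


def _require_weight(entry: BofEntry) -> float:
    if entry.molecular_weight is None:
        raise ValueError("consumed BOF entry lacks a molecular weight")
    return entry.molecular_weight


@dataclass
class ScalingTable:
    """Per-group positive scale factors, one column per environment label."""

    columns: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for label, factors in self.columns.items():
            missing = set(GROUPS) - set(factors)
            if missing:
                raise ValueError(
                    f"scaling column {label!r} missing groups: {sorted(missing)}"
                )
            bad = [g for g, f in factors.items() if not f > 0]
            if bad:
                raise ValueError(f"non-positive factors in column {label!r}: {bad}")

    def factor(self, environment: str, group: str) -> float:
        try:
            column = self.columns[environment]
        except KeyError:
            raise KeyError(f"unknown scaling environment {environment!r}") from None
        try:
            return column[group]
        except KeyError:
            raise KeyError(f"unknown group {group!r}") from None


def limitation_scaling_table() -> ScalingTable:
    """Default group scaling for nitrogen-limited (NL) and carbon-limited (CL)
    environments relative to the unlimited (UL) reference."""
    return ScalingTable(
        columns={
            "UL": {g: 1.0 for g in GROUPS},
            "NL": {
                "DNA": 1.1, "RNA": 0.86, "Protein": 0.2, "Lipid": 20.0,
                "Carbohydrates": 15.0, "Energy": 4.0, "Co-factors": 4.0,
                "Ions": 1.0, "Others": 3.0,
            },
            "CL": {
                "DNA": 1.9, "RNA": 1.6, "Protein": 3.5, "Lipid": 0.26,
                "Carbohydrates": 0.2, "Energy": 0.5, "Co-factors": 3.0,
                "Ions": 1.1, "Others": 2.0,
            },
        }
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def mean_bofs(a: BiomassComposition, b: BiomassComposition) -> BiomassComposition:
    """Compound-wise arithmetic mean over the union of both compound sets.

    A compound absent from one input contributes coefficient zero there, so
    its mean is half the coefficient of the input carrying it.
    """
    entries: dict[str, BofEntry] = {}
    for cid in sorted(set(a.entries) | set(b.entries)):
        ea, eb = a.entries.get(cid), b.entries.get(cid)
        if ea is not None and eb is not None:
            if ea.side != eb.side:
                raise ValueError(f"side conflict for compound {cid!r} in mean_bofs")
            if ea.group != eb.group:
                raise ValueError(f"group conflict for compound {cid!r} in mean_bofs")
            template = ea
            coef = (ea.coefficient + eb.coefficient) / 2.0
            if (
                ea.molecular_weight is None
                and eb.molecular_weight is not None
            ):
                template = eb
        else:
            template = ea if ea is not None else eb
            coef = template.coefficient / 2.0
        entries[cid] = replace(template, coefficient=coef)
    return BiomassComposition(entries=entries, label=f"mean({a.label},{b.label})")


def remove_compound(bof: BiomassComposition, compound: str) -> BiomassComposition:
    if compound not in bof.entries:
        raise KeyError(f"compound {compound!r} not present in BOF {bof.label!r}")
    entries = {k: e for k, e in bof.entries.items() if k != compound}
    return BiomassComposition(entries=entries, label=bof.label)


def bof_mass(bof: BiomassComposition, exclude: Iterable[str] = ()) -> float:
    """Consumed-side mass in g gCDW^-1 per unit flux: sum of alpha_i * MW_i / 1000.

    *exclude* optionally drops an explicit compound set (e.g. an ATP-hydrolysis
    quadruple) from the sum for macromolecule-only normalization conventions.
    """
    excl = set(exclude)
    missing = [
        cid
        for cid, e in bof.consumed().items()
        if cid not in excl and e.molecular_weight is None
    ]
    if missing:
        raise ValueError(f"missing molecular weights for compounds: {sorted(missing)}")
    return sum(
        e.coefficient * e.molecular_weight / 1000.0
        for cid, e in bof.consumed().items()
        if cid not in excl
    )


def normalize_unit_mass(
    bof: BiomassComposition, exclude: Iterable[str] = ()
) -> BiomassComposition:
    """Rescale all coefficients (both sides) so the consumed mass is 1 g gCDW^-1."""
    mass = bof_mass(bof, exclude=exclude)
    if mass <= 0:
        raise ValueError(f"BOF {bof.label!r} has zero consumed mass; cannot normalize")
    return bof.scaled(1.0 / mass)


def scale_groups(
    bof: BiomassComposition,
    table: ScalingTable,
    environment: str,
    exclude: Iterable[str] = (),
) -> BiomassComposition:
    """Multiply each coefficient by its group's factor, then renormalize to
    unit mass.  The compound set is preserved exactly."""
    entries = {}
    for cid, e in bof.entries.items():
        entries[cid] = replace(
            e, coefficient=e.coefficient * table.factor(environment, e.group)
        )
    scaled = BiomassComposition(entries=entries, label=f"{bof.label}:{environment}")
    return normalize_unit_mass(scaled, exclude=exclude)


def composition_from_reaction(
    model: MetabolicModel,
    rxn_id: str,
    groups: Mapping[str, str],
    label: str | None = None,
) -> BiomassComposition:
    """Extract a BiomassComposition from a model's biomass pseudo-reaction.

    Negative stoichiometric coefficients become consumed entries, positive
    ones produced entries; weights come from the metabolites.
    """
    if not model.has_reaction(rxn_id):
        raise KeyError(f"model has no reaction {rxn_id!r}")
    rxn = model.reaction(rxn_id)
    entries: dict[str, BofEntry] = {}
    for cid, coef in rxn.stoichiometry.items():
        met = model.metabolite(cid)
        try:
            mw = metabolite_weight(met)
        except ValueError:
            mw = None
        entries[cid] = BofEntry(
            coefficient=abs(coef),
            side=CONSUMED if coef < 0 else PRODUCED,
            group=groups.get(cid, "Others"),
            molecular_weight=mw,
        )
    return BiomassComposition(entries=entries, label=label or rxn_id)


def build_artificial_bofs(
    model: MetabolicModel,
    table: ScalingTable,
    drop: Iterable[str] = (),
    source_reactions: tuple[str, str] = ("BIOMASS_A", "BIOMASS_B"),
    groups: Mapping[str, str] | None = None,
    environments: tuple[str, str] = ("NL", "CL"),
    exclude: Iterable[str] = (),
) -> dict[str, BiomassComposition]:
    """Run the full artificial-BOF pipeline.

    Mean the two source biomass reactions, drop the listed compounds,
    normalize to unit mass (the UL reference), then apply the per-environment
    group scaling columns.  Returns {"UL": ..., "NL": ..., "CL": ...}.
    """
    groups = groups or {}
    for rid in source_reactions:
        if not model.has_reaction(rid):
            raise KeyError(f"model lacks source biomass reaction {rid!r}")
    a = composition_from_reaction(model, source_reactions[0], groups)
    b = composition_from_reaction(model, source_reactions[1], groups)
    merged = mean_bofs(a, b)
    for cid in drop:
        merged = remove_compound(merged, cid)
    ul = normalize_unit_mass(merged, exclude=exclude)
    ul.label = "UL"
    out = {"UL": ul}
    for env in environments:
        scaled = scale_groups(ul, table, env, exclude=exclude)
        scaled.label = env
        out[env] = scaled
    return out


def bof_to_reaction(bof: BiomassComposition, rxn_id: str) -> Reaction:
    """Render a composition as an irreversible biomass pseudo-reaction."""
    stoich = {}
    for cid, e in bof.entries.items():
        stoich[cid] = -e.coefficient if e.side == CONSUMED else e.coefficient
    return Reaction(rxn_id, stoich, lower_bound=0.0, upper_bound=1000.0, name=bof.label)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["compound_id", "side", "coefficient", "group", "molecular_weight"]


def write_bof_table(bof: BiomassComposition, path: str) -> None:
    rows = [
        {
            "compound_id": cid,
            "side": e.side,
            "coefficient": e.coefficient,
            "group": e.group,
            "molecular_weight": e.molecular_weight,
        }
        for cid, e in sorted(bof.entries.items())
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bof_table(path: str, label: str = "") -> BiomassComposition:
    df = pd.read_csv(path, sep="\t")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"BOF table {path} missing columns: {sorted(missing)}")
    entries = {}
    for row in df.itertuples(index=False):
        mw = row.molecular_weight
        entries[row.compound_id] = BofEntry(
            coefficient=float(row.coefficient),
            side=str(row.side),
            group=str(row.group),
            molecular_weight=None if pd.isna(mw) else float(mw),
        )
    return BiomassComposition(entries=entries, label=label)
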