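"""Constraint-based model containers, readers/writers, and toy fixture models.

The in-memory representation is deliberately small: plain dataclasses holding
the stoichiometric structure, bounds, GPR strings, and a linear objective.
SBML (Level 3 + FBC) I/O is delegated to COBRApy; the JSON dialect mirrors
the community COBRA-JSON schema so files interoperate with other tools.

Sign conventions: an exchange reaction has a single metabolite with
stoichiometric coefficient -1, and *uptake* is a negative flux through it.
User-facing "uptake rates" are positive magnitudes.
"""

from __future__ import annotations

import copy as _copy
import json
import re
from dataclasses import dataclass, field

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelFormatError",
    "ToySpec",
    "read_model",
    "write_model",
    "make_toy_model",
    "formula_weight",
    "metabolite_weight",
    "TOY_GROUPS",
]


class ModelFormatError(ValueError):
    """Raised when a model file fails to parse or violates invariants."""


# Monoisotopic-free average atomic masses (g/mol), enough for typical
# metabolic-model formulas.
_ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "K": 39.098, "Na": 22.990, "Mg": 24.305, "Ca": 40.078,
    "Fe": 55.845, "Zn": 65.38, "Cl": 35.45, "Cu": 63.546, "Mn": 54.938,
    "Co": 58.933, "Mo": 95.95, "Ni": 58.693, "Se": 78.971, "W": 183.84,
    "R": 0.0, "X": 0.0,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def formula_weight(formula: str) -> float:
    """Average molecular weight (g/mol) of a chemical formula string."""
    if not formula:
        raise ValueError("empty formula")
    consumed = 0
    weight = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        element, count = match.groups()
        if element not in _ATOMIC_MASS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        weight += _ATOMIC_MASS[element] * (float(count) if count else 1.0)
        consumed += len(match.group(0))
    if consumed != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return weight


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    molecular_weight: float | None = None
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.molecular_weight is not None and self.molecular_weight < 0:
            raise ValueError(f"negative molecular weight on {self.id}")


def metabolite_weight(met: Metabolite) -> float:
    """Resolve a metabolite's molecular weight (explicit value wins over formula)."""
    if met.molecular_weight is not None:
        return met.molecular_weight
    if met.formula:
        return formula_weight(met.formula)
    raise ValueError(f"no molecular weight available for metabolite {met.id!r}")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1 and next(iter(self.stoichiometry.values())) < 0

    def genes(self) -> set[str]:
        if not self.gpr:
            return set()
        return set(re.findall(r"[A-Za-z_][\w.\-]*", self.gpr)) - {"and", "or", "AND", "OR"}


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except (AttributeError, KeyError):
            self._reindex()
            return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except (AttributeError, KeyError):
            self._reindex()
            return self._rxn_index[rxn_id]

    def has_reaction(self, rxn_id: str) -> bool:
        self._reindex()
        return rxn_id in self._rxn_index

    def _reindex(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- mutation --------------------------------------------------------
    def add_reaction(self, rxn: Reaction) -> None:
        if any(r.id == rxn.id for r in self.reactions):
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        missing = set(rxn.stoichiometry) - {m.id for m in self.metabolites}
        if missing:
            raise ValueError(
                f"reaction {rxn.id} references unknown metabolites: {sorted(missing)}"
            )
        self.reactions.append(rxn)
        for g in sorted(rxn.genes() - set(self.genes)):
            self.genes.append(g)
        self._reindex()

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            raise ValueError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            raise ValueError("duplicate reaction ids")
        met_set = set(met_ids)
        gene_set = set(self.genes)
        for r in self.reactions:
            missing = set(r.stoichiometry) - met_set
            if missing:
                raise ValueError(
                    f"reaction {r.id} references unknown metabolites: {sorted(missing)}"
                )
            missing_genes = r.genes() - gene_set
            if missing_genes:
                raise ValueError(
                    f"reaction {r.id} GPR uses undeclared genes: {sorted(missing_genes)}"
                )
        bad_obj = set(self.objective) - set(rxn_ids)
        if bad_obj:
            raise ValueError(f"objective references unknown reactions: {sorted(bad_obj)}")
        self._reindex()


# ---------------------------------------------------------------------------
# JSON dialect (COBRA-JSON compatible subset)
# ---------------------------------------------------------------------------

def _to_json_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "version": "1",
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "notes": (
                    {"molecular_weight": m.molecular_weight}
                    if m.molecular_weight is not None
                    else {}
                ),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
                "objective_coefficient": model.objective.get(r.id, 0.0),
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in model.genes],
    }


def _from_json_dict(data: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                molecular_weight=(m.get("notes") or {}).get("molecular_weight"),
                formula=m.get("formula"),
            )
            for m in data["metabolites"]
        ]
        rxns = []
        objective: dict[str, float] = {}
        for r in data["reactions"]:
            rxns.append(
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                    lower_bound=float(r["lower_bound"]),
                    upper_bound=float(r["upper_bound"]),
                    gpr=r.get("gene_reaction_rule", ""),
                    name=r.get("name", ""),
                )
            )
            coef = float(r.get("objective_coefficient", 0.0))
            if coef:
                objective[r["id"]] = coef
        genes = [g["id"] for g in data.get("genes", [])]
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed JSON model: {exc}") from exc
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective=objective,
        id=data.get("id", "model"),
    )


# ---------------------------------------------------------------------------
# SBML via COBRApy
# ---------------------------------------------------------------------------

def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment, formula=m.formula or None
        )
        if m.molecular_weight is not None:
            cmet.notes["molecular_weight"] = repr(m.molecular_weight)
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        crxn = cobra.Reaction(
            r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
        )
        crxns.append(crxn)
    cm.add_reactions(crxns)
    for r, crxn in zip(model.reactions, crxns):
        crxn.add_metabolites({cmets[k]: v for k, v in r.stoichiometry.items()})
        if r.gpr:
            crxn.gene_reaction_rule = r.gpr
    if model.objective:
        cm.objective = {cm.reactions.get_by_id(k): v for k, v in model.objective.items()}
    return cm


def _from_cobra(cm) -> MetabolicModel:
    mets = []
    for m in cm.metabolites:
        mw = m.notes.get("molecular_weight")
        mets.append(
            Metabolite(
                id=m.id,
                name=m.name or "",
                compartment=m.compartment or "c",
                molecular_weight=float(mw) if mw is not None else None,
                formula=m.formula or None,
            )
        )
    rxns = []
    objective: dict[str, float] = {}
    for r in cm.reactions:
        if r.lower_bound is None or r.upper_bound is None:
            raise ModelFormatError(f"reaction {r.id} lacks FBC bounds")
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: v for m, v in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=r.gene_reaction_rule or "",
                name=r.name or "",
            )
        )
        coef = float(r.objective_coefficient)
        if coef:
            objective[r.id] = coef
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=[g.id for g in cm.genes],
        objective=objective,
        id=cm.id or "model",
    )


def read_model(path: str, format: str | None = None) -> MetabolicModel:
    """Read an SBML-FBC or COBRA-JSON model from *path*.

    The format is inferred from the extension when not given explicitly.
    """
    fmt = format or ("json" if str(path).endswith(".json") else "sbml-fbc")
    if fmt == "json":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"invalid JSON in {path}: {exc}") from exc
        return _from_json_dict(data)
    if fmt == "sbml-fbc":
        from cobra.io import read_sbml_model

        try:
            cm = read_sbml_model(str(path))
        except Exception as exc:  # libsbml raises a zoo of types
            raise ModelFormatError(f"SBML parse failure for {path}: {exc}") from exc
        return _from_cobra(cm)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str, format: str | None = None) -> None:
    """Write *model* to *path* as SBML-FBC or COBRA-JSON (round-trip safe)."""
    model.validate()
    fmt = format or ("json" if str(path).endswith(".json") else "sbml-fbc")
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_to_json_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
        return
    if fmt == "sbml-fbc":
        from cobra.io import write_sbml_model

        write_sbml_model(_to_cobra(model), str(path))
        return
    raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# Toy fixture models
# ---------------------------------------------------------------------------

#: Macromolecular group of each toy biomass compound.
TOY_GROUPS = {
    "prot_c": "Protein",
    "carb_c": "Carbohydrates",
    "lipid_c": "Lipid",
    "atp_c": "Energy",
}


@dataclass
class ToySpec:
    """Parameters of the deterministic toy network.

    topology "core" builds a respiro-fermentative network with two biomass
    reactions; "chain" builds the minimal uptake -> convert -> biomass chain
    whose LP optimum is ``yield_factor * uptake_bound`` by inspection.
    """

    topology: str = "core"
    glucose_capacity: float = 10.0
    ammonium_capacity: float = 10.0
    oxygen_capacity: float = 1000.0
    uptake_bound: float = 10.0   # chain topology
    yield_factor: float = 0.5    # chain topology
    coefficient_jitter: float = 0.0  # relative jitter on BOF coefficients

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _chain_model(spec: ToySpec) -> MetabolicModel:
    mets = [
        Metabolite("s_e", compartment="e", molecular_weight=100.0),
        Metabolite("b_c", compartment="c", molecular_weight=100.0),
    ]
    rxns = [
        Reaction("EX_s_e", {"s_e": -1.0}, lower_bound=-spec.uptake_bound),
        Reaction("CONV", {"s_e": -1.0, "b_c": spec.yield_factor}, gpr="gCONV"),
        Reaction("BIOMASS", {"b_c": -1.0}),
    ]
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=["gCONV"],
        objective={"BIOMASS": 1.0},
        id="toy_chain",
    )


def _core_model(spec: ToySpec, seed: int) -> MetabolicModel:
    import numpy as np

    mets = [
        Metabolite("glc__D_e", "D-glucose", "e", formula="C6H12O6"),
        Metabolite("nh4_e", "ammonium", "e", formula="NH4"),
        Metabolite("o2_e", "oxygen", "e", formula="O2"),
        Metabolite("co2_e", "carbon dioxide", "e", formula="CO2"),
        Metabolite("ac_e", "acetate", "e", formula="C2H3O2"),
        Metabolite("glc__D_c", "D-glucose", "c", formula="C6H12O6"),
        Metabolite("nh4_c", "ammonium", "c", formula="NH4"),
        Metabolite("o2_c", "oxygen", "c", formula="O2"),
        Metabolite("co2_c", "carbon dioxide", "c", formula="CO2"),
        Metabolite("ac_c", "acetate", "c", formula="C2H3O2"),
        Metabolite("atp_c", "energy token", "c", molecular_weight=507.0),
        Metabolite("prot_c", "protein unit", "c", molecular_weight=110.0),
        Metabolite("carb_c", "carbohydrate unit", "c", molecular_weight=162.0),
        Metabolite("lipid_c", "lipid unit", "c", molecular_weight=600.0),
    ]
    rxns = [
        Reaction("EX_glc__D_e", {"glc__D_e": -1.0}, lower_bound=-spec.glucose_capacity),
        Reaction("EX_nh4_e", {"nh4_e": -1.0}, lower_bound=-spec.ammonium_capacity),
        Reaction("EX_o2_e", {"o2_e": -1.0}, lower_bound=-spec.oxygen_capacity),
        Reaction("EX_co2_e", {"co2_e": -1.0}, lower_bound=0.0),
        Reaction("EX_ac_e", {"ac_e": -1.0}, lower_bound=0.0),
        Reaction("GLCt", {"glc__D_e": -1.0, "glc__D_c": 1.0}, gpr="gGLCt"),
        Reaction("NH4t", {"nh4_e": -1.0, "nh4_c": 1.0}, gpr="gNH4t"),
        Reaction("O2t", {"o2_e": -1.0, "o2_c": 1.0}),
        Reaction("CO2t", {"co2_c": -1.0, "co2_e": 1.0}),
        Reaction("ACt", {"ac_c": -1.0, "ac_e": 1.0}),
        # full oxidation: C6 + 6 O2 -> 6 CO2, 20 energy tokens
        Reaction(
            "RESP",
            {"glc__D_c": -1.0, "o2_c": -6.0, "co2_c": 6.0, "atp_c": 20.0},
            gpr="gRESP1 or gRESP2",
        ),
        # overflow: C6 -> 2 acetate + 2 CO2, 4 energy tokens, no oxygen
        Reaction(
            "OVERFLOW",
            {"glc__D_c": -1.0, "ac_c": 2.0, "co2_c": 2.0, "atp_c": 4.0},
            gpr="gOVER",
        ),
        Reaction(
            "PROTS",
            {"glc__D_c": -1.0, "nh4_c": -4.0, "atp_c": -2.0, "prot_c": 1.0},
            gpr="gPROT1 and gPROT2",
        ),
        Reaction("CARBS", {"glc__D_c": -1.0, "atp_c": -1.0, "carb_c": 1.0}, gpr="gCARB"),
        Reaction(
            "LIPIDS", {"glc__D_c": -3.0, "atp_c": -2.0, "lipid_c": 1.0}, gpr="gLIP"
        ),
        # non-growth energy dissipation; keeps forced carbon uptake feasible
        Reaction("ATPM", {"atp_c": -1.0}),
    ]
    # Two biomass drains differing in group composition: A protein-heavy,
    # B carbohydrate-heavy.  Coefficients are in mmol per unit flux; the
    # BOF-construction pipeline renormalizes to 1 g gCDW^-1.
    base_a = {"prot_c": 6.0, "carb_c": 0.5, "lipid_c": 0.2, "atp_c": 30.0}
    base_b = {"prot_c": 1.0, "carb_c": 4.0, "lipid_c": 0.3, "atp_c": 20.0}
    if spec.coefficient_jitter:
        rng = np.random.default_rng(seed)
        for comp in (base_a, base_b):
            for k in comp:
                comp[k] *= 1.0 + spec.coefficient_jitter * rng.uniform(-1.0, 1.0)
    rxns.append(Reaction("BIOMASS_A", {k: -v for k, v in base_a.items()}))
    rxns.append(Reaction("BIOMASS_B", {k: -v for k, v in base_b.items()}))
    genes = sorted({g for r in rxns for g in r.genes()})
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective={"BIOMASS_A": 1.0},
        id="toy_core",
    )


def make_toy_model(spec: ToySpec | None = None, seed: int = 0) -> MetabolicModel:
    """Deterministically build a small test model from *spec* and *seed*.

    The closed state v = 0 is always feasible; with default open exchanges
    the core model grows through either biomass drain.
    """
    spec = spec or ToySpec()
    if spec.topology == "chain":
        return _chain_model(spec)
    if spec.topology == "core":
        return _core_model(spec, seed)
    raise ValueError(f"unknown toy topology {spec.topology!r}")
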