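"""Core data structures and I/O for constraint-based metabolic models.

A metabolic model is the substrate of every downstream computation: a
stoichiometric matrix ``S`` (metabolites x reactions), flux bounds, and a
biomass objective.  Flux balance analysis and flux sampling both operate on
the polytope ``{v : S v = 0, lb <= v <= ub}``.

Sign convention: for exchange reactions a negative flux is uptake and a
positive flux is secretion.  Report-facing "uptake rates" are therefore
presented as positive magnitudes by the callers in :mod:`phaflux.physiology`
and :mod:`phaflux.contextualize`.

The JSON dialect mirrors the community COBRA layout (``metabolites`` /
``reactions`` with ``lower_bound`` / ``upper_bound`` / ``objective_coefficient``)
so externally curated genome-scale models such as iJN1411 can be loaded
unchanged.  Fields honoured on load: metabolite ``id``, ``name``, ``formula``,
``compartment``; reaction ``id``, ``name``, ``metabolites``, ``lower_bound``,
``upper_bound``, ``subsystem``, ``objective_coefficient``.  Everything else
(gene rules, annotations, notes) is ignored.  SBML Level 3 read support is
optional and routed through cobrapy when it is importable.
"""

from __future__ import annotations

import copy as _copy
import json
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

#: LP feasibility tolerance used by the HiGHS solver and reported in
#: :class:`FluxSolution` metadata.
SOLVER_FEASIBILITY_TOL = 1e-9

#: Net elemental imbalance above which a reaction is reported by
#: :func:`check_mass_balance`.
MASS_BALANCE_TOL = 1e-9

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelValidationError(ValueError):
    """A model violates a structural invariant (duplicate ids, dangling
    stoichiometry keys, inverted bounds, ...)."""


class ModelParseError(ValueError):
    """A model file could not be parsed; the message names the offending
    element."""


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse an elemental formula like ``C8H15O2`` into element counts.

    Counts are non-negative integers; an omitted count means 1.
    Raises :class:`ModelParseError` on anything that is not a sequence of
    element symbols with optional integer counts.
    """
    if not formula:
        return {}
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ModelParseError(
                f"formula {formula!r}: unparseable at position {pos}"
            )
        pos = match.end()
        element, num = match.groups()
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ModelParseError(f"formula {formula!r}: unparseable at position {pos}")
    return counts


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` is optional; when present it must parse to non-negative
    integer element counts (used by :func:`check_mass_balance`).
    """

    id: str
    name: str = ""
    formula: Optional[str] = None
    compartment: str = "c"

    def elements(self) -> Dict[str, int]:
        return parse_formula(self.formula) if self.formula else {}


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds in mmol gCDW^-1 h^-1.

    ``stoichiometry`` maps metabolite id to a signed real coefficient
    (negative = consumed).  Exchange (boundary) reactions touch exactly one
    metabolite and are exempt from elemental balancing.
    """

    id: str
    stoichiometry: Dict[str, float]
    lb: float = -1000.0
    ub: float = 1000.0
    name: str = ""
    subsystem: str = ""
    is_exchange: bool = False

    def validate(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lb > self.ub:
            raise ModelValidationError(
                f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id!r} touches "
                f"{len(self.stoichiometry)} metabolites (expected 1)"
            )

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub


@dataclass
class MetabolicModel:
    """A full constraint-based model: metabolites, reactions, objective."""

    metabolites: List[Metabolite]
    reactions: List[Reaction]
    objective_id: str
    name: str = "model"
    _met_index: Dict[str, int] = field(default_factory=dict, repr=False)
    _rxn_index: Dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- structural validation -------------------------------------------
    def validate(self) -> None:
        self._met_index = {}
        for i, met in enumerate(self.metabolites):
            if met.id in self._met_index:
                raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
            self._met_index[met.id] = i
        self._rxn_index = {}
        for j, rxn in enumerate(self.reactions):
            if rxn.id in self._rxn_index:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            self._rxn_index[rxn.id] = j
            rxn.validate()
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared "
                        f"metabolite {met_id!r}"
                    )
        if self.objective_id not in self._rxn_index:
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )

    # -- lookups ----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise KeyError(f"no metabolite {met_id!r} in model {self.name!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.name!r}")

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    # -- numerics ---------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with shape (n_metabolites, n_reactions)."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                S[self._met_index[met_id], j] = coef
        return S

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions], dtype=float)
        ub = np.array([r.ub for r in self.reactions], dtype=float)
        return lb, ub

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        c[self._rxn_index[self.objective_id]] = 1.0
        return c

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]


@dataclass
class FluxSolution:
    """Result of one linear-programming solve.

    When ``status == "optimal"`` the flux vector satisfies ``S v = 0`` and
    the bounds within the solver feasibility tolerance, and
    ``objective_value`` is in h^-1 when the objective is a biomass reaction.
    """

    status: str  # optimal | infeasible | unbounded
    objective_value: Optional[float]
    fluxes: Dict[str, float]
    feasibility_tol: float = SOLVER_FEASIBILITY_TOL

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


# ---------------------------------------------------------------------------
# JSON / SBML I/O
# ---------------------------------------------------------------------------

def _looks_like_exchange(rxn_id: str, stoich: Dict[str, float]) -> bool:
    return len(stoich) == 1


def model_to_dict(model: MetabolicModel) -> dict:
    """Serialize to the COBRA-JSON dialect (plus an explicit ``objective``)."""
    return {
        "id": model.name,
        "version": "1",
        "objective": model.objective_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula or "",
                "compartment": m.compartment,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lb,
                "upper_bound": r.ub,
                "subsystem": r.subsystem,
                "gene_reaction_rule": "",
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [],
        "compartments": {
            c: c for c in sorted({m.compartment for m in model.metabolites})
        },
    }


def model_from_dict(data: dict) -> MetabolicModel:
    if "metabolites" not in data or "reactions" not in data:
        raise ModelParseError("model JSON lacks 'metabolites' or 'reactions'")
    metabolites = []
    for entry in data["metabolites"]:
        if "id" not in entry:
            raise ModelParseError(f"metabolite without id: {entry!r}")
        metabolites.append(
            Metabolite(
                id=entry["id"],
                name=entry.get("name", ""),
                formula=entry.get("formula") or None,
                compartment=entry.get("compartment", "c"),
            )
        )
    reactions = []
    objective_from_coef = None
    for entry in data["reactions"]:
        if "id" not in entry:
            raise ModelParseError(f"reaction without id: {entry!r}")
        if "metabolites" not in entry:
            raise ModelParseError(f"reaction {entry['id']!r} lacks stoichiometry")
        stoich = {k: float(v) for k, v in entry["metabolites"].items()}
        reactions.append(
            Reaction(
                id=entry["id"],
                name=entry.get("name", ""),
                stoichiometry=stoich,
                lb=float(entry.get("lower_bound", -1000.0)),
                ub=float(entry.get("upper_bound", 1000.0)),
                subsystem=entry.get("subsystem", "") or "",
                is_exchange=_looks_like_exchange(entry["id"], stoich),
            )
        )
        if float(entry.get("objective_coefficient", 0.0)) != 0.0:
            objective_from_coef = entry["id"]
    objective = data.get("objective") or objective_from_coef
    if objective is None:
        raise ModelParseError("no objective reaction declared in model JSON")
    try:
        return MetabolicModel(
            metabolites=metabolites,
            reactions=reactions,
            objective_id=objective,
            name=data.get("id", data.get("name", "model")),
        )
    except ModelValidationError as err:
        raise ModelParseError(str(err)) from err


def load_model(path: str, format: str = "json") -> MetabolicModel:
    """Load a model from ``path``.

    ``format="json"`` (canonical) reads the documented COBRA-JSON dialect;
    ``format="sbml"`` is an optional read-only path through cobrapy.
    """
    if format == "json":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as err:
            raise ModelParseError(f"{path}: invalid JSON ({err})") from err
        return model_from_dict(data)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def _load_sbml(path: str) -> MetabolicModel:
    try:
        import cobra.io
    except ImportError as err:  # pragma: no cover - environment dependent
        raise ModelParseError(
            "SBML support requires cobrapy; install the 'cobra' package or "
            "convert the model to the JSON dialect"
        ) from err
    cm = cobra.io.read_sbml_model(path)
    metabolites = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            formula=m.formula or None,
            compartment=m.compartment or "c",
        )
        for m in cm.metabolites
    ]
    objective = None
    reactions = []
    for r in cm.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        reactions.append(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry=stoich,
                lb=float(r.lower_bound),
                ub=float(r.upper_bound),
                subsystem=r.subsystem or "",
                is_exchange=len(stoich) == 1,
            )
        )
        if r.objective_coefficient:
            objective = r.id
    if objective is None:
        raise ModelParseError(f"{path}: SBML model declares no objective")
    return MetabolicModel(
        metabolites=metabolites, reactions=reactions, objective_id=objective,
        name=cm.id or "model",
    )


def write_model(model: MetabolicModel, path: str) -> None:
    """Write the JSON dialect; ``load_model(write_model(m))`` round-trips
    ids, bounds and coefficients bit-exactly."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Structural checks and edits
# ---------------------------------------------------------------------------

def check_mass_balance(
    model: MetabolicModel,
    tol: float = MASS_BALANCE_TOL,
    exempt: Iterable[str] = (),
) -> List[str]:
    """Return ids of elementally unbalanced interior reactions.

    For every non-exchange reaction other than the biomass objective (and any
    ids in ``exempt``, e.g. sink/demand pseudo-reactions), the net
    stoichiometric sum of every element must vanish within ``tol``.  A missing
    formula on a checked reaction raises, naming the metabolite.
    """
    exempt_ids = set(exempt) | {model.objective_id}
    unbalanced = []
    for rxn in model.reactions:
        if rxn.is_exchange or rxn.id in exempt_ids:
            continue
        net: Dict[str, float] = {}
        for met_id, coef in rxn.stoichiometry.items():
            met = model.metabolite(met_id)
            if not met.formula:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: metabolite {met_id!r} has no formula; "
                    "cannot check mass balance"
                )
            for element, count in met.elements().items():
                net[element] = net.get(element, 0.0) + coef * count
        if any(abs(v) > tol for v in net.values()):
            unbalanced.append(rxn.id)
    return unbalanced


def knockout(model: MetabolicModel, reaction_id: str) -> MetabolicModel:
    """Return a copy of ``model`` with ``reaction_id`` clamped to zero flux.

    The input model is never mutated.  Unknown ids raise ``KeyError``.
    """
    model.reaction(reaction_id)  # raise early on unknown id
    out = model.copy()
    rxn = out.reaction(reaction_id)
    rxn.lb = 0.0
    rxn.ub = 0.0
    return out
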