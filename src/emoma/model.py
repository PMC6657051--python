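"""Metabolic-model data structures and editing primitives.

A :class:`MetabolicModel` is the stoichiometric description of a metabolic
network at steady state: a matrix ``S`` (metabolites x reactions), flux
bounds ``a <= v <= b`` and an objective vector ``c`` (normally the biomass
pseudo-reaction, whose flux is the specific growth rate in 1/h).  Fluxes are
in mmol/gDCW/h throughout.

Sign conventions
----------------
Exchange and demand pseudo-reactions touch exactly one metabolite.  For an
exchange written ``met -> (nothing)`` (coefficient -1, the COBRA community
convention) negative flux is uptake and positive flux is secretion; an
exchange written ``(nothing) -> met`` (coefficient +1) has the opposite
orientation.  Code that needs "the uptake direction" should use
:meth:`Reaction.import_sign`, which returns the sign of the flux that moves
the metabolite *into* the system and is correct for both orientations.
"""

from __future__ import annotations

import copy as _copy
import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

logger = logging.getLogger("emoma")

DEFAULT_BOUND = 1000.0

REACTION_KINDS = ("internal", "exchange", "demand", "biomass", "orphan")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelError(ValueError):
    """Raised when a model, file or patch violates an invariant."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``"C6H12O6"`` into element counts.

    Counts must be non-negative integers; anything else (charges, decimal
    coefficients, stray characters) raises :class:`ModelError`.
    """
    if not formula:
        raise ModelError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ModelError(f"cannot parse formula {formula!r} at position {pos}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise ModelError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def carbon_count(formula: str | None) -> int:
    """Number of carbon atoms in a formula; 0 for an empty formula."""
    if not formula:
        return 0
    return parse_formula(formula).get("C", 0)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None

    def validate(self) -> None:
        if not self.id:
            raise ModelError("metabolite with empty id")
        if self.formula is not None:
            parse_formula(self.formula)


@dataclass
class Reaction:
    """One column of the stoichiometric matrix.

    ``stoichiometry`` maps metabolite id -> coefficient (negative =
    consumed).  ``kind`` classifies the pseudo-reaction role; ``orphan``
    marks an internal reaction with no gene association (not addressable by
    genetic engineering).
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gene_rule: str | None = None
    kind: str = "internal"

    def validate(self) -> None:
        if not self.id:
            raise ModelError("reaction with empty id")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r} has lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.kind not in REACTION_KINDS:
            raise ModelError(f"reaction {self.id!r} has unknown kind {self.kind!r}")
        if self.kind in ("exchange", "demand") and len(self.stoichiometry) != 1:
            raise ModelError(
                f"{self.kind} reaction {self.id!r} must touch exactly one "
                f"metabolite, got {len(self.stoichiometry)}"
            )

    @property
    def is_boundary(self) -> bool:
        return self.kind in ("exchange", "demand")

    @property
    def is_orphan(self) -> bool:
        return self.gene_rule is None or self.gene_rule == ""

    def boundary_metabolite(self) -> tuple[str, float]:
        """(metabolite id, coefficient) of a single-metabolite reaction."""
        if len(self.stoichiometry) != 1:
            raise ModelError(f"reaction {self.id!r} is not a boundary reaction")
        (met, coef), = self.stoichiometry.items()
        return met, coef

    def import_sign(self) -> float:
        """Sign of the flux direction that imports the metabolite.

        +1 if positive flux produces the metabolite into the system
        (orientation ``(nothing) -> met``), -1 for the COBRA ``met ->
        (nothing)`` orientation where uptake is negative flux.
        """
        _, coef = self.boundary_metabolite()
        return 1.0 if coef > 0 else -1.0


@dataclass
class MetabolicModel:
    """An ordered collection of metabolites and reactions.

    Ordering is preserved exactly as constructed (file order for models read
    from disk); all matrices and vectors index off that order so solver
    behaviour is reproducible under degeneracy.
    """

    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    # -- indexing -------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"unknown metabolite {met_id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"unknown reaction {rxn_id!r}")

    def reaction_index(self, rxn_id: str) -> int:
        for i, r in enumerate(self.reactions):
            if r.id == rxn_id:
                return i
        raise KeyError(f"unknown reaction {rxn_id!r}")

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    # -- matrix views ---------------------------------------------------
    @property
    def S(self) -> sparse.csc_matrix:
        """Stoichiometric matrix, metabolites x reactions."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                if met not in met_index:
                    raise ModelError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
                rows.append(met_index[met])
                cols.append(j)
                data.append(float(coef))
        return sparse.csc_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    @property
    def a(self) -> np.ndarray:
        return np.array([r.lower_bound for r in self.reactions], dtype=float)

    @property
    def b(self) -> np.ndarray:
        return np.array([r.upper_bound for r in self.reactions], dtype=float)

    @property
    def c(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        for i, r in enumerate(self.reactions):
            if r.kind == "biomass":
                c[i] = 1.0
        return c

    @property
    def objective_id(self) -> str:
        ids = [r.id for r in self.reactions if r.kind == "biomass"]
        if not ids:
            raise ModelError("no objective defined (no biomass reaction)")
        if len(ids) > 1:
            raise ModelError(f"multiple objective reactions: {ids}")
        return ids[0]

    def boundary_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_boundary]

    # -- lifecycle ------------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def validate(self) -> None:
        if not self.reactions:
            raise ModelError("empty model")
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            raise ModelError("duplicate metabolite ids")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelError("duplicate reaction ids")
        for m in self.metabolites:
            m.validate()
        known = set(met_ids)
        for r in self.reactions:
            r.validate()
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )
        self.objective_id  # raises if absent or ambiguous


# ---------------------------------------------------------------------------
# Patch edits
# ---------------------------------------------------------------------------

@dataclass
class SetBounds:
    reaction_id: str
    lower_bound: float
    upper_bound: float


@dataclass
class RemoveReaction:
    reaction_id: str


@dataclass
class AddReaction:
    reaction: Reaction


@dataclass
class SetObjective:
    reaction_id: str


Edit = SetBounds | RemoveReaction | AddReaction | SetObjective


@dataclass
class ModelPatch:
    """An ordered list of model edits, applied atomically by :func:`apply_patch`."""

    edits: list[Edit] = field(default_factory=list)

    @classmethod
    def from_dicts(cls, items: Iterable[Mapping]) -> "ModelPatch":
        """Build a patch from JSON-style edit objects keyed by ``op``."""
        edits: list[Edit] = []
        for i, item in enumerate(items):
            op = item.get("op")
            if op == "set_bounds":
                edits.append(
                    SetBounds(item["reaction_id"], float(item["lower_bound"]),
                              float(item["upper_bound"]))
                )
            elif op == "remove_reaction":
                edits.append(RemoveReaction(item["reaction_id"]))
            elif op == "add_reaction":
                r = item["reaction"]
                edits.append(AddReaction(Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    lower_bound=float(r.get("lower_bound", 0.0)),
                    upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                    gene_rule=r.get("gene_rule"),
                    kind=r.get("kind", "internal"),
                )))
            elif op == "set_objective":
                edits.append(SetObjective(item["reaction_id"]))
            else:
                raise ModelError(f"edit {i}: unknown op {op!r}")
        return cls(edits)


def apply_patch(model: MetabolicModel, patch: ModelPatch) -> MetabolicModel:
    """Apply a :class:`ModelPatch`, returning a new model (input untouched).

    Edits are applied in order; a failing edit raises :class:`ModelError`
    naming its index and the offending id.
    """
    new = model.copy()
    for i, edit in enumerate(patch.edits):
        try:
            _apply_edit(new, edit)
        except (KeyError, ModelError) as exc:
            raise ModelError(f"patch edit {i} ({type(edit).__name__}): {exc}") from exc
    new.validate()
    return new


def _apply_edit(model: MetabolicModel, edit: Edit) -> None:
    if isinstance(edit, SetBounds):
        rxn = model.reaction(edit.reaction_id)
        if edit.lower_bound > edit.upper_bound:
            raise ModelError(
                f"bounds [{edit.lower_bound}, {edit.upper_bound}] inverted for "
                f"{edit.reaction_id!r}"
            )
        rxn.lower_bound = edit.lower_bound
        rxn.upper_bound = edit.upper_bound
    elif isinstance(edit, RemoveReaction):
        idx = model.reaction_index(edit.reaction_id)
        del model.reactions[idx]
    elif isinstance(edit, AddReaction):
        if model.has_reaction(edit.reaction.id):
            raise ModelError(f"reaction {edit.reaction.id!r} already present")
        edit.reaction.validate()
        for met in edit.reaction.stoichiometry:
            if not any(m.id == met for m in model.metabolites):
                model.metabolites.append(Metabolite(id=met))
        model.reactions.append(_copy.deepcopy(edit.reaction))
    elif isinstance(edit, SetObjective):
        target = model.reaction(edit.reaction_id)  # raises if unknown
        for r in model.reactions:
            if r.kind == "biomass":
                r.kind = "internal"
        target.kind = "biomass"
    else:  # pragma: no cover
        raise ModelError(f"unknown edit type {type(edit).__name__}")


def add_demand_reaction(model: MetabolicModel, metabolite_id: str) -> MetabolicModel:
    """Add an irreversible demand sink ``DM_<metabolite_id>`` with bounds [0, 1000].

    Demand pseudo-reactions drain an intracellular metabolite and are the
    standard device for modelling accumulation of a storage compound (here,
    TAG) without putting it in the biomass equation.  Idempotent: a second
    call returns an identical model and logs a warning.
    """
    model.metabolite(metabolite_id)  # raises KeyError if unknown
    new_id = f"DM_{metabolite_id}"
    new = model.copy()
    if new.has_reaction(new_id):
        warnings.warn(
            f"demand reaction {new_id!r} already present; no-op", stacklevel=2
        )
        return new
    new.reactions.append(Reaction(
        id=new_id,
        name=f"{metabolite_id} demand",
        stoichiometry={metabolite_id: -1.0},
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
        kind="demand",
    ))
    new.validate()
    return new
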