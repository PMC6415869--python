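"""Core containers for constraint-based metabolic networks.

The in-memory model is deliberately small: metabolites, reactions with flux
bounds (mmol·gDW⁻¹·hr⁻¹), and a sparse stoichiometric matrix S (metabolite ×
reaction). Exchange reactions follow the BiGG export-positive convention: an
exchange touches exactly one metabolite with coefficient −1, so negative flux
is uptake and "uptake" is reported as the non-negative number u = −v
throughout the public interface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "Medium",
    "FormulaError",
    "ModelFormatError",
    "parse_formula",
    "carbon_count",
]

DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """An elemental formula string could not be parsed."""


class ModelFormatError(ValueError):
    """A model file or in-memory model violates a structural invariant."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula (e.g. ``C6H12O6``) into element counts.

    Counts are non-negative integers; an empty formula maps to ``{}``.
    Raises :class:`FormulaError` on anything that is not a plain
    element/count sequence (charges, parentheses and isotope notation are
    rejected rather than guessed at).
    """
    if formula is None:
        return {}
    formula = formula.strip()
    if not formula:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(f"unparseable formula {formula!r} at position {pos}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(f"unparseable formula {formula!r} at position {pos}")
    return counts


@dataclass(frozen=True)
class Metabolite:
    id: str
    formula: str = ""
    compartment: str = ""

    def element_counts(self) -> dict[str, int]:
        return parse_formula(self.formula)


def carbon_count(met: Metabolite) -> int:
    """Number of carbon atoms in the metabolite's formula (0 if absent)."""
    return parse_formula(met.formula).get("C", 0)


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""
    is_spontaneous: bool = False
    #: "exchange" | "demand" | "sink" when the source format says so; empty
    #: means classify structurally (single-metabolite ⇒ exchange)
    boundary_type: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelFormatError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions touch exactly one metabolite.

        Compartment suffixes are not trusted; single-metabolite stoichiometry
        is the detection rule — unless the source format explicitly marked the
        reaction as a demand or sink (cytosolic drains are boundary reactions
        but not exchanges).
        """
        if self.boundary_type:
            return self.boundary_type == "exchange"
        return len(self.stoich) == 1

    def copy(self) -> "Reaction":
        return replace(self, stoich=dict(self.stoich))


class MetabolicNetwork:
    """A stoichiometric model with bounds and a designated biomass reaction."""

    def __init__(
        self,
        reactions: list[Reaction],
        metabolites: list[Metabolite],
        biomass_reaction_id: str,
        objective_id: str | None = None,
        id: str = "model",
    ) -> None:
        self.id = id
        self.reactions = list(reactions)
        self.metabolites = list(metabolites)
        met_ids = {m.id for m in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ModelFormatError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelFormatError("duplicate reaction ids")
        for rxn in self.reactions:
            missing = set(rxn.stoich) - met_ids
            if missing:
                raise ModelFormatError(
                    f"reaction {rxn.id} references undeclared metabolites: "
                    f"{sorted(missing)}"
                )
        if biomass_reaction_id not in set(rxn_ids):
            raise ModelFormatError(
                f"biomass reaction {biomass_reaction_id!r} not in model"
            )
        self.biomass_reaction_id = biomass_reaction_id
        self.objective_id = objective_id or biomass_reaction_id

    # -- indexing -----------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id}") from None

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"no metabolite {met_id!r} in model {self.id}")

    def _rxn_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    # -- stoichiometry ------------------------------------------------------
    def stoichiometry(self) -> sparse.csr_matrix:
        """Sparse S matrix, metabolite × reaction, in list order."""
        met_pos = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoich.items():
                rows.append(met_pos[met_id])
                cols.append(j)
                vals.append(float(coeff))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    # -- boundary -----------------------------------------------------------
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchange_metabolite(self, rxn_id: str) -> Metabolite:
        rxn = self.reaction(rxn_id)
        if not rxn.is_exchange:
            raise ValueError(f"{rxn_id} is not an exchange reaction")
        (met_id,) = rxn.stoich
        return self.metabolite(met_id)

    # -- mutation helpers (all return copies; networks are value-like) ------
    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            [r.copy() for r in self.reactions],
            list(self.metabolites),
            self.biomass_reaction_id,
            self.objective_id,
            id=self.id,
        )

    def with_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicNetwork":
        """Copy with bounds replaced for the listed reactions."""
        net = self.copy()
        index = net._rxn_index()
        for rxn_id, (lb, ub) in bounds.items():
            rxn = index[rxn_id]
            if lb > ub:
                raise ModelFormatError(f"reaction {rxn_id}: bounds ({lb}, {ub}) invalid")
            rxn.lower_bound = float(lb)
            rxn.upper_bound = float(ub)
        return net

    def knock_out(self, rxn_ids) -> "MetabolicNetwork":
        """Copy with the listed reactions' bounds forced to zero."""
        return self.with_bounds({rid: (0.0, 0.0) for rid in rxn_ids})

    def without_reactions(self, rxn_ids) -> "MetabolicNetwork":
        drop = set(rxn_ids)
        if self.biomass_reaction_id in drop:
            raise ModelFormatError("cannot delete the biomass reaction")
        kept = [r.copy() for r in self.reactions if r.id not in drop]
        used = set()
        for r in kept:
            used.update(r.stoich)
        mets = [m for m in self.metabolites if m.id in used]
        return MetabolicNetwork(
            kept, mets, self.biomass_reaction_id, self.objective_id, id=self.id
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicNetwork {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites>"
        )


@dataclass(frozen=True)
class Medium:
    """Growth medium as max-uptake allowances on exchange reactions.

    Values are non-negative maximum uptake fluxes; applying a medium sets the
    listed exchanges' lower bounds to −value and closes every unlisted
    exchange (lower bound 0). Upper (secretion) bounds are never touched.
    """

    uptake_bounds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rxn_id, value in self.uptake_bounds.items():
            if value < 0:
                raise ValueError(f"medium uptake for {rxn_id} must be >= 0, got {value}")

    def items(self):
        return self.uptake_bounds.items()

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.uptake_bounds
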