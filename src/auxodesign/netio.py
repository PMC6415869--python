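"""Model I/O, media handling, and chemical-formula queries.

SBML (Level 3 + FBC) and COBRA-JSON files are read and written through
cobrapy; this module converts between cobra's containers and the package's
lightweight :class:`~auxodesign.core.MetabolicNetwork`.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import yaml

from .core import (
    Medium,
    MetabolicNetwork,
    Metabolite,
    ModelFormatError,
    Reaction,
    carbon_count,
)

__all__ = [
    "load_model",
    "write_model",
    "from_cobra",
    "to_cobra",
    "apply_medium",
    "load_medium",
    "glucose_m9_medium",
    "list_target_exchanges",
]

_SPONTANEOUS_MARKERS = ("s0001", "spontaneous")


def from_cobra(model) -> MetabolicNetwork:
    """Convert a cobra.Model into a MetabolicNetwork.

    The biomass reaction is taken from the model objective if it names exactly
    one reaction; otherwise the caller must set it explicitly.
    """
    metabolites = [
        Metabolite(m.id, m.formula or "", m.compartment or "") for m in model.metabolites
    ]
    # cobra distinguishes exchanges from cytosolic demand/sink drains (both
    # are single-metabolite boundary reactions); keep its classification so
    # demands never masquerade as supplementable exchanges
    boundary_types: dict[str, str] = {}
    for kind, group in (
        ("exchange", model.exchanges),
        ("demand", model.demands),
        ("sink", model.sinks),
    ):
        for r in group:
            boundary_types[r.id] = kind
    reactions = []
    for r in model.reactions:
        gene_ids = {g.id.lower() for g in r.genes}
        # BiGG models mark spontaneous reactions with the pseudo-gene s0001
        spont = any(g in _SPONTANEOUS_MARKERS for g in gene_ids)
        reactions.append(
            Reaction(
                id=r.id,
                stoich={m.id: c for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                subsystem=r.subsystem or "",
                is_spontaneous=spont,
                boundary_type=boundary_types.get(r.id, ""),
            )
        )
    objective_rxns = [
        r.id for r in model.reactions if abs(r.objective_coefficient) > 0
    ]
    if len(objective_rxns) != 1:
        raise ModelFormatError(
            "could not identify a unique biomass reaction from the model "
            f"objective (candidates: {objective_rxns}); set one explicitly "
            "via MetabolicNetwork(..., biomass_reaction_id=...)"
        )
    return MetabolicNetwork(
        reactions, metabolites, biomass_reaction_id=objective_rxns[0], id=model.id
    )


def to_cobra(net: MetabolicNetwork):
    """Convert a MetabolicNetwork into a cobra.Model (for writing / oracles)."""
    import cobra

    model = cobra.Model(net.id)
    mets = {
        m.id: cobra.Metabolite(m.id, formula=m.formula or None, compartment=m.compartment or "c")
        for m in net.metabolites
    }
    model.add_metabolites(list(mets.values()))
    rxns = []
    for r in net.reactions:
        rxn = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxn.subsystem = r.subsystem
        rxns.append(rxn)
    model.add_reactions(rxns)
    for r in net.reactions:
        model.reactions.get_by_id(r.id).add_metabolites(
            {mets[mid]: c for mid, c in r.stoich.items()}
        )
    model.objective = net.biomass_reaction_id
    return model


def load_model(path, format: str | None = None) -> MetabolicNetwork:
    """Read an SBML-FBC or COBRA-JSON model file.

    ``format`` is ``"sbml"`` or ``"json"``; when omitted it is inferred from
    the file suffix.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format not in ("sbml", "json"):
        raise ValueError(f"unknown model format {format!r}; expected 'sbml' or 'json'")
    try:
        if format == "json":
            model = cobra.io.load_json_model(str(path))
        else:
            model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ModelFormatError(f"could not parse {path} as {format}: {exc}") from exc
    return from_cobra(model)


def write_model(net: MetabolicNetwork, path, format: str | None = None) -> None:
    """Write a MetabolicNetwork to SBML-FBC or COBRA-JSON."""
    import cobra.io

    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    model = to_cobra(net)
    if format == "json":
        cobra.io.save_json_model(model, str(path))
    elif format == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


def apply_medium(net: MetabolicNetwork, medium: Medium) -> MetabolicNetwork:
    """Return a copy of ``net`` with the medium's uptake allowances applied.

    Listed exchanges get lower_bound = −max_uptake; every unlisted exchange is
    closed to uptake (lower bound 0). Secretion (upper) bounds are untouched.
    Idempotent by construction.
    """
    exchange_ids = {r.id for r in net.exchanges()}
    unknown = set(medium.uptake_bounds) - exchange_ids
    if unknown:
        raise KeyError(
            f"medium names non-exchange or missing reactions: {sorted(unknown)}"
        )
    bounds = {}
    for rxn in net.exchanges():
        uptake = medium.uptake_bounds.get(rxn.id, 0.0)
        bounds[rxn.id] = (-float(uptake), rxn.upper_bound)
    return net.with_bounds(bounds)


def load_medium(path) -> Medium:
    """Read a medium from a YAML/JSON map {exchange_id: max_uptake}."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            data = json.load(fh)
        else:
            data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: medium file must be a flat mapping")
    return Medium({str(k): float(v) for k, v in data.items()})


def glucose_m9_medium() -> Medium:
    """The packaged glucose M9 minimal medium (model defaults, O2 capped at 20)."""
    ref = importlib.resources.files("auxodesign").joinpath("data/glucose_M9.yaml")
    data = yaml.safe_load(ref.read_text())
    return Medium({str(k): float(v) for k, v in data.items()})


def list_target_exchanges(net: MetabolicNetwork) -> list[str]:
    """Exchange reactions whose metabolite contains at least one carbon atom.

    These are the candidate auxotrophy targets; the list is sorted by reaction
    id so it is invariant under reaction reordering.
    """
    targets = []
    for rxn in net.exchanges():
        met = net.exchange_metabolite(rxn.id)
        if carbon_count(met) >= 1:
            targets.append(rxn.id)
    return sorted(targets)
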