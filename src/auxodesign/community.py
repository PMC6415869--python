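"""Two-strain abundance-scaled community flux balance analysis.

Each strain keeps its own compartment (fluxes in mmol·gDW_strain⁻¹·hr⁻¹) and
trades metabolites through a shared extracellular compartment (fluxes in
mmol·gDW_community⁻¹·hr⁻¹). A strain's boundary fluxes are scaled by its
fractional dry-weight abundance X on the shared side: a secretion link for
strain 1 reads

    metabolite_strain1  →  X₁ · metabolite_shared

so one unit of strain-level flux delivers X₁ community-level units, which is
exactly the mass balance for a culture that is fraction X₁ strain 1. The two
strains' growth rates are constrained equal (serial-passage co-cultures that
persist must grow at the same average rate), and community growth is the
common rate, maximized by LP.

Cross-feeding is restricted: a strain may take up from the shared pool only
metabolites in the allowed cross-feed set or supplied by the shared medium;
secretion into the pool is always open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_BOUND, Medium, MetabolicNetwork, Metabolite, Reaction
from .lp import optimize_flux

__all__ = [
    "CommunityComposition",
    "CommunityModel",
    "SweepResult",
    "UnboundedCommunityError",
    "build_community",
    "community_growth",
    "sweep_composition",
    "restrict_crossfeed",
    "add_export_route",
    "DEFAULT_COMPOSITION_GRID",
]

DEFAULT_COMPOSITION_GRID = tuple(np.linspace(0.05, 0.95, 10).round(10))

_GROWTH_COUPLING_MET = "growth_coupling"


class UnboundedCommunityError(RuntimeError):
    """Community growth is unbounded; a substrate cap is required for M-models."""


@dataclass(frozen=True)
class CommunityComposition:
    X_strain1: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.X_strain1 <= 1.0:
            raise ValueError("X_strain1 must be in [0, 1]")

    @property
    def X_strain2(self) -> float:
        return 1.0 - self.X_strain1


@dataclass
class CommunityModel:
    network: MetabolicNetwork
    composition: CommunityComposition
    allowed_crossfeed: frozenset[str]
    shared_medium: Medium
    # link reaction ids keyed by (strain prefix, base metabolite id)
    links: dict[tuple[str, str], str] = field(default_factory=dict)
    shared_exchanges: dict[str, str] = field(default_factory=dict)
    biomass_ids: tuple[str, str] = ("", "")

    def to_json(self, path) -> None:
        """Export as COBRA-JSON; abundance factors are baked into stoichiometry."""
        from .netio import write_model

        write_model(self.network, path, format="json")


def _strain_compartment(net: MetabolicNetwork, knockouts, prefix: str):
    """Namespace a strain model and split off its boundary metabolites."""
    ko = net.knock_out(knockouts) if knockouts else net.copy()
    mets = [
        Metabolite(f"{prefix}{m.id}", m.formula, f"{prefix}{m.compartment}")
        for m in ko.metabolites
    ]
    reactions = []
    exchange_mets: dict[str, str] = {}  # base metabolite id -> strain met id
    for r in ko.reactions:
        if r.is_exchange:
            (met_id,) = r.stoich
            exchange_mets[met_id] = f"{prefix}{met_id}"
            # strain-level exchange is replaced by a link to the shared pool
            continue
        reactions.append(
            Reaction(
                id=f"{prefix}{r.id}",
                stoich={f"{prefix}{mid}": c for mid, c in r.stoich.items()},
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                subsystem=r.subsystem,
                is_spontaneous=r.is_spontaneous,
            )
        )
    return ko, mets, reactions, exchange_mets


def build_community(
    netA: MetabolicNetwork,
    knockoutsA,
    netB: MetabolicNetwork,
    knockoutsB,
    composition: CommunityComposition | float,
    allowed_crossfeed,
    shared_medium: Medium,
) -> CommunityModel:
    """Assemble the two-compartment community model at a fixed composition.

    ``allowed_crossfeed`` lists base metabolite ids (extracellular) that either
    strain may take up from the shared pool; the shared medium's metabolites
    are implicitly uptakable as well. Refuses compositions of exactly 0 or 1
    (community growth there is 0 by convention — see
    :func:`sweep_composition`) and cross-feed metabolites that a strain has no
    exchange for.
    """
    if not isinstance(composition, CommunityComposition):
        composition = CommunityComposition(float(composition))
    if composition.X_strain1 in (0.0, 1.0):
        raise ValueError(
            "composition 0 or 1 is a monoculture; community growth is 0 by "
            "convention and the model is not built"
        )
    allowed_crossfeed = frozenset(allowed_crossfeed)

    strains = [
        ("S1_", netA, knockoutsA, composition.X_strain1),
        ("S2_", netB, knockoutsB, composition.X_strain2),
    ]
    all_mets: list[Metabolite] = []
    all_rxns: list[Reaction] = []
    links: dict[tuple[str, str], str] = {}
    shared_needed: dict[str, Metabolite] = {}
    exchange_sets = []

    for prefix, net, kos, X in strains:
        ko, mets, reactions, exchange_mets = _strain_compartment(net, kos, prefix)
        exchange_sets.append(set(exchange_mets))
        all_mets.extend(mets)
        all_rxns.extend(reactions)
        for base_id, strain_met in exchange_mets.items():
            shared_id = base_id
            if shared_id not in shared_needed:
                base = ko.metabolite(base_id)
                shared_needed[shared_id] = Metabolite(shared_id, base.formula, "shared")
            uptake_open = base_id in allowed_crossfeed or _medium_covers(
                shared_medium, net, base_id
            )
            links[(prefix, base_id)] = f"{prefix}link_{base_id}"
            all_rxns.append(
                Reaction(
                    id=f"{prefix}link_{base_id}",
                    # positive flux = secretion into the shared pool
                    stoich={strain_met: -1.0, shared_id: X},
                    lower_bound=-DEFAULT_BOUND if uptake_open else 0.0,
                    upper_bound=DEFAULT_BOUND,
                )
            )

    missing = [
        (prefix, met)
        for met in allowed_crossfeed
        for prefix, ex_set in zip(("S1_", "S2_"), exchange_sets)
        if met not in ex_set
    ]
    if missing:
        details = ", ".join(f"{p.rstrip('_')} lacks {m}" for p, m in missing)
        raise ValueError(f"cross-feed metabolite without a transport route: {details}")

    all_mets.extend(shared_needed.values())

    # shared-compartment exchanges: uptake per the shared medium, secretion open
    shared_exchanges: dict[str, str] = {}
    medium_by_met = _medium_uptake_by_metabolite(shared_medium, netA, netB)
    for shared_id in shared_needed:
        ex_id = f"EX_shared_{shared_id}"
        shared_exchanges[shared_id] = ex_id
        all_rxns.append(
            Reaction(
                id=ex_id,
                stoich={shared_id: -1.0},
                lower_bound=-medium_by_met.get(shared_id, 0.0),
                upper_bound=DEFAULT_BOUND,
            )
        )

    # equal-growth contract: a balancing row forces v_biomass,1 = v_biomass,2
    coupling = Metabolite(_GROWTH_COUPLING_MET, "", "shared")
    all_mets.append(coupling)
    b1 = f"S1_{netA.biomass_reaction_id}"
    b2 = f"S2_{netB.biomass_reaction_id}"
    for rxn in all_rxns:
        if rxn.id == b1:
            rxn.stoich[_GROWTH_COUPLING_MET] = 1.0
        elif rxn.id == b2:
            rxn.stoich[_GROWTH_COUPLING_MET] = -1.0

    network = MetabolicNetwork(
        all_rxns,
        all_mets,
        biomass_reaction_id=b1,
        id=f"community_{netA.id}_{netB.id}",
    )
    return CommunityModel(
        network=network,
        composition=composition,
        allowed_crossfeed=allowed_crossfeed,
        shared_medium=shared_medium,
        links=links,
        shared_exchanges=shared_exchanges,
        biomass_ids=(b1, b2),
    )


def _medium_covers(medium: Medium, net: MetabolicNetwork, base_met_id: str) -> bool:
    for ex_id, value in medium.items():
        if value > 0 and net.has_reaction(ex_id):
            (mid,) = net.reaction(ex_id).stoich
            if mid == base_met_id:
                return True
    return False


def _medium_uptake_by_metabolite(medium, netA, netB) -> dict[str, float]:
    out: dict[str, float] = {}
    for ex_id, value in medium.items():
        for net in (netA, netB):
            if net.has_reaction(ex_id):
                (mid,) = net.reaction(ex_id).stoich
                out[mid] = max(out.get(mid, 0.0), float(value))
                break
        else:
            raise KeyError(f"shared medium names unknown exchange {ex_id}")
    return out


def community_growth(model: CommunityModel) -> float:
    """LP maximum of the common growth rate (hr⁻¹); 0 if infeasible."""
    res = optimize_flux(model.network, model.biomass_ids[0], sense="max")
    if res.status == "unbounded":
        raise UnboundedCommunityError(
            "community growth is unbounded; cap a substrate (e.g. glucose) in "
            "the shared medium when using metabolism-only models"
        )
    if not res.ok:
        return 0.0
    return max(0.0, res.objective)


@dataclass(frozen=True)
class SweepResult:
    grid: tuple[float, ...]
    growth: tuple[float, ...]
    optimal_X: float
    near_optimal_set: tuple[float, ...]
    viable: bool

    def to_frame(self) -> pd.DataFrame:
        near = set(self.near_optimal_set)
        return pd.DataFrame(
            {
                "X_strain1": self.grid,
                "growth_rate": self.growth,
                "near_optimal": [x in near for x in self.grid],
            }
        )


def sweep_composition(
    netA: MetabolicNetwork,
    knockoutsA,
    netB: MetabolicNetwork,
    knockoutsB,
    allowed_crossfeed,
    shared_medium: Medium,
    grid=DEFAULT_COMPOSITION_GRID,
    near_optimal_fraction: float = 0.95,
) -> SweepResult:
    """Maximize community growth at each interior composition on the grid.

    Endpoints X ∈ {0, 1} are appended with growth 0 (an auxotroph monoculture
    cannot grow). The near-optimal set collects grid compositions whose growth
    is at least ``near_optimal_fraction`` of the maximum. A sweep where no
    composition grows is flagged non-viable.
    """
    interior = sorted(float(x) for x in grid)
    if any(not 0.0 < x < 1.0 for x in interior):
        raise ValueError("grid compositions must lie strictly between 0 and 1")
    xs, growths = [0.0], [0.0]
    for x in interior:
        model = build_community(
            netA, knockoutsA, netB, knockoutsB, x, allowed_crossfeed, shared_medium
        )
        xs.append(x)
        growths.append(community_growth(model))
    xs.append(1.0)
    growths.append(0.0)

    gmax = max(growths)
    if gmax <= 0.0:
        return SweepResult(tuple(xs), tuple(growths), 0.0, (), viable=False)
    optimal_X = xs[int(np.argmax(growths))]
    near = tuple(
        x for x, g in zip(xs, growths) if g >= near_optimal_fraction * gmax
    )
    return SweepResult(tuple(xs), tuple(growths), optimal_X, near, viable=True)


def restrict_crossfeed(
    model: CommunityModel, metabolite: str, also_keep=()
) -> CommunityModel:
    """Close all cross-feed uptake links except the named metabolite.

    ``also_keep`` lists reciprocal metabolites the partner strain still needs
    (e.g. the EBC partner's own rescuer when probing which metabolite feeds
    the MSE strain). Medium-supplied uptake links stay open. Returns a new
    model; the input is not mutated.
    """
    keep = {metabolite, *also_keep}
    unknown = keep - {met for (_, met) in model.links}
    if unknown:
        raise KeyError(f"no transport link for metabolite(s): {sorted(unknown)}")
    bounds = {}
    net = model.network
    for (prefix, met), link_id in model.links.items():
        rxn = net.reaction(link_id)
        if met in model.allowed_crossfeed and met not in keep:
            bounds[link_id] = (0.0, rxn.upper_bound)
    return CommunityModel(
        network=net.with_bounds(bounds),
        composition=model.composition,
        allowed_crossfeed=frozenset(keep & model.allowed_crossfeed),
        shared_medium=model.shared_medium,
        links=dict(model.links),
        shared_exchanges=dict(model.shared_exchanges),
        biomass_ids=model.biomass_ids,
    )


def add_export_route(
    net: MetabolicNetwork, met_id: str, extracellular_id: str | None = None
) -> MetabolicNetwork:
    """Give a metabolite with no export path a diffusion route to the boundary.

    Adds a reversible transport from ``met_id`` to an extracellular copy plus
    an exchange (closed to uptake), so the metabolite can be secreted and
    cross-fed. Used to patch genome-scale models where a compound has an
    importer but no exporter.
    """
    net = net.copy()
    ex_met_id = extracellular_id or f"{met_id}__export_e"
    base = net.metabolite(met_id)
    new_mets = list(net.metabolites)
    if all(m.id != ex_met_id for m in new_mets):
        new_mets.append(Metabolite(ex_met_id, base.formula, "e"))
    new_rxns = [r.copy() for r in net.reactions]
    new_rxns.append(
        Reaction(
            id=f"T_{met_id}_export",
            stoich={met_id: -1.0, ex_met_id: 1.0},
            lower_bound=-DEFAULT_BOUND,
            upper_bound=DEFAULT_BOUND,
        )
    )
    new_rxns.append(
        Reaction(
            id=f"EX_{ex_met_id}",
            stoich={ex_met_id: -1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
    )
    return MetabolicNetwork(
        new_rxns, new_mets, net.biomass_reaction_id, net.objective_id, id=net.id
    )
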