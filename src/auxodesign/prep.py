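"""FVA-based model reduction and knockout-candidate filtering.

Before the bilevel knockout search, the model is tightened by flux
variability analysis (reactions that can carry no flux are deleted, all
others get their bounds clamped to the FVA range), and the knockout-candidate
pool is pruned by five exclusion rules: known model false positives,
rich-media-essential reactions, a subsystem blocklist, reactions touching any
metabolite with more than ten carbons, and spontaneous reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import MetabolicNetwork, carbon_count
from .lp import InfeasibleModelError, fva

__all__ = [
    "FVAResult",
    "CandidateSet",
    "SUBSYSTEM_BLOCKLIST",
    "ZERO_FLUX_TOLERANCE",
    "reduce_by_fva",
    "filter_knockout_candidates",
    "load_reaction_id_list",
]

# Subsystems whose reactions are never knockout candidates: membrane/envelope
# assembly, transport, exchanges, and tRNA charging. Knockouts there either
# break the model unphysically or are not realizable as single-enzyme
# deletions.
SUBSYSTEM_BLOCKLIST = frozenset(
    {
        "Cell Envelope Biosynthesis",
        "Exchange",
        "Inorganic Ion Transport and Metabolism",
        "Lipopolysaccharide Biosynthesis / Recycling",
        "Murein Biosynthesis",
        "Murein Recycling",
        "Transport, Inner Membrane",
        "Transport, Outer Membrane",
        "Transport, Outer Membrane Porin",
        "tRNA Charging",
    }
)

ZERO_FLUX_TOLERANCE = 1e-6  # mmol/gDW/hr; below this a reaction is dead
MAX_CANDIDATE_CARBONS = 10


@dataclass(frozen=True)
class FVAResult:
    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for rid, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"FVA range for {rid} inverted: ({lo}, {hi})")


@dataclass
class CandidateSet:
    """Knockout candidates plus a log of why each excluded reaction fell out.

    Every model reaction appears in exactly one of ``knockout_candidates`` and
    ``exclusion_log`` (which maps reaction id → first matching criterion).
    """

    knockout_candidates: list[str]
    exclusion_log: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.knockout_candidates) & set(self.exclusion_log)
        if overlap:
            raise ValueError(f"reactions both candidate and excluded: {sorted(overlap)}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reaction_id": rid, "status": "candidate", "criterion": ""}
            for rid in self.knockout_candidates
        ] + [
            {"reaction_id": rid, "status": "excluded", "criterion": why}
            for rid, why in sorted(self.exclusion_log.items())
        ]
        return pd.DataFrame(rows, columns=["reaction_id", "status", "criterion"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def reduce_by_fva(
    net: MetabolicNetwork, zero_tolerance: float = ZERO_FLUX_TOLERANCE
) -> MetabolicNetwork:
    """Clamp every reaction's bounds to its FVA range; delete dead reactions.

    FVA runs with the biomass lower bound relaxed to 0 (no growth fraction is
    imposed, so low-growth states survive the reduction); the incoming biomass
    bounds — typically already fixed to the design growth rate — are restored
    on the reduced model. Raises :class:`InfeasibleModelError`, leaving the
    input untouched, if the model is infeasible.
    """
    biomass = net.reaction(net.biomass_reaction_id)
    bio_bounds = (biomass.lower_bound, biomass.upper_bound)
    relaxed = net.with_bounds({net.biomass_reaction_id: (0.0, bio_bounds[1])})
    ranges = fva(relaxed)  # raises before any mutation if infeasible

    dead = [
        rid
        for rid, (lo, hi) in ranges.items()
        if abs(lo) < zero_tolerance and abs(hi) < zero_tolerance
        and rid != net.biomass_reaction_id
    ]
    reduced = relaxed.without_reactions(dead)
    new_bounds = {}
    for rxn in reduced.reactions:
        lo, hi = ranges[rxn.id]
        new_bounds[rxn.id] = (lo, hi)
    new_bounds[net.biomass_reaction_id] = bio_bounds
    return reduced.with_bounds(new_bounds)


def filter_knockout_candidates(
    net: MetabolicNetwork,
    essential_rich_media: set[str] = frozenset(),
    false_positives: set[str] = frozenset(),
) -> CandidateSet:
    """Split the model's reactions into knockout candidates and exclusions.

    The first matching criterion is logged:

    1. ``false_positive`` — in the supplied model false-positive list;
    2. ``essential_rich_media`` — in the supplied rich-media essentiality list;
    3. ``blocked_subsystem`` — annotated subsystem on the blocklist;
    4. ``large_metabolite`` — any participating metabolite with > 10 carbons;
    5. ``spontaneous`` — reaction occurs without an enzyme.

    The biomass reaction is never a candidate (logged as ``biomass``).
    An empty candidate set is legal.
    """
    candidates: list[str] = []
    excluded: dict[str, str] = {}
    met_lookup = {m.id: m for m in net.metabolites}
    for rxn in net.reactions:
        if rxn.id == net.biomass_reaction_id:
            excluded[rxn.id] = "biomass"
        elif rxn.id in false_positives:
            excluded[rxn.id] = "false_positive"
        elif rxn.id in essential_rich_media:
            excluded[rxn.id] = "essential_rich_media"
        elif rxn.subsystem in SUBSYSTEM_BLOCKLIST or (
            rxn.is_exchange and "Exchange" in SUBSYSTEM_BLOCKLIST
        ):
            excluded[rxn.id] = "blocked_subsystem"
        elif any(
            carbon_count(met_lookup[mid]) > MAX_CANDIDATE_CARBONS for mid in rxn.stoich
        ):
            excluded[rxn.id] = "large_metabolite"
        elif rxn.is_spontaneous:
            excluded[rxn.id] = "spontaneous"
        else:
            candidates.append(rxn.id)
    return CandidateSet(knockout_candidates=candidates, exclusion_log=excluded)


def load_reaction_id_list(path) -> set[str]:
    """Read a plain-text reaction-id list (one id per line, '#' comments)."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return ids
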