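"""Rescue-metabolite enumeration and auxotroph classification.

A knockout design is an auxotroph if it cannot grow on the base medium. Its
rescue profile is found by opening each carbon exchange, one at a time, and
testing whether growth becomes feasible; each rescuer is annotated with the
minimum uptake flux the strain needs. Designs rescued by exactly one
metabolite are essential-biomass-component (EBC) specific auxotrophs, by two
to four are EBC semi-specific, and by five or more are major-subsystem
eliminations (MSE) — knockouts that sever a whole biosynthetic subsystem so
many alternative inputs can patch the gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import MetabolicNetwork
from .lp import is_feasible, optimize_flux
from .netio import list_target_exchanges
from .optaux import KnockoutDesign, OptAuxSolution

__all__ = [
    "RescueProfile",
    "DesignClass",
    "UnrescuableDesignError",
    "rescue_metabolites",
    "average_required_uptake",
    "classify_design",
    "dedupe_auxotrophies",
    "profiles_to_frame",
]

DEFAULT_SUPPLEMENT_CAP = 10.0


class UnrescuableDesignError(ValueError):
    """An auxotrophic design that no single supplement can rescue."""


@dataclass(frozen=True)
class RescueProfile:
    design: KnockoutDesign
    growth_rate_tested: float
    rescuers: dict[str, float]  # exchange id -> minimum required uptake
    is_auxotroph: bool


@dataclass(frozen=True)
class DesignClass:
    label: str  # EBC_specific | EBC_semi_specific | MSE | not_auxotrophic
    n_rescuers: int


def rescue_metabolites(
    net: MetabolicNetwork,
    design: KnockoutDesign,
    growth_rate: float = 0.1,
    supplement_cap: float = DEFAULT_SUPPLEMENT_CAP,
) -> RescueProfile:
    """Find every carbon metabolite whose individual uptake restores growth.

    ``net`` must already carry the base medium; supplements are the carbon
    exchanges the medium leaves closed, opened one at a time up to
    ``supplement_cap``. A design that grows unsupplemented is reported with
    ``is_auxotroph=False`` and no rescuers.
    """
    ko = net.knock_out(design.knocked_out)
    fixed_growth = {ko.biomass_reaction_id: (growth_rate, growth_rate)}
    if is_feasible(ko, extra_bounds=fixed_growth):
        return RescueProfile(design, growth_rate, {}, is_auxotroph=False)

    rescuers: dict[str, float] = {}
    for ex_id in list_target_exchanges(ko):
        rxn = ko.reaction(ex_id)
        if rxn.lower_bound < 0:  # already open in the medium
            continue
        opened = dict(fixed_growth)
        opened[ex_id] = (-supplement_cap, rxn.upper_bound)
        res = optimize_flux(ko, ex_id, sense="max", extra_bounds=opened)
        if res.ok:
            uptake = max(0.0, -res.objective)
            if uptake > 0:
                rescuers[ex_id] = uptake
    return RescueProfile(design, growth_rate, rescuers, is_auxotroph=True)


def average_required_uptake(profile: RescueProfile) -> float:
    """Arithmetic mean of the per-rescuer minimum uptakes (mmol·gDW⁻¹·hr⁻¹)."""
    if not profile.rescuers:
        raise ValueError("rescue profile has no rescuers; average is undefined")
    values = list(profile.rescuers.values())
    return sum(values) / len(values)


def classify_design(profile: RescueProfile) -> DesignClass:
    """Pure classification from (is_auxotroph, number of rescuers)."""
    n = len(profile.rescuers)
    if not profile.is_auxotroph:
        return DesignClass("not_auxotrophic", n)
    if n == 0:
        raise UnrescuableDesignError(
            f"design {sorted(profile.design.knocked_out)} is auxotrophic but no "
            "single supplement restores growth"
        )
    if n == 1:
        return DesignClass("EBC_specific", 1)
    if n <= 4:
        return DesignClass("EBC_semi_specific", n)
    return DesignClass("MSE", n)


def dedupe_auxotrophies(
    solutions: list[OptAuxSolution], profiles: list[RescueProfile]
) -> list[dict]:
    """Group knockout sets that produce the same auxotrophy.

    Two designs are the same auxotrophy when their rescuer *sets* are
    identical (required uptakes may differ). Returns one group per unique
    rescuer set, each listing its member designs, ordered by first appearance.
    """
    if len(solutions) != len(profiles):
        raise ValueError("solutions and profiles must align")
    groups: dict[frozenset, dict] = {}
    for sol, prof in zip(solutions, profiles):
        key = frozenset(prof.rescuers)
        if key not in groups:
            groups[key] = {"rescuers": sorted(key), "members": []}
        groups[key]["members"].append(sol)
    return list(groups.values())


def profiles_to_frame(
    profiles: list[RescueProfile],
) -> pd.DataFrame:
    """Serialize profiles to a tidy table (design, rescuer, min uptake, class)."""
    rows = []
    for prof in profiles:
        label = classify_design(prof).label if (prof.rescuers or not prof.is_auxotroph) else "unrescuable"
        design = "+".join(sorted(prof.design.knocked_out)) or "(none)"
        if prof.rescuers:
            for ex_id, uptake in sorted(prof.rescuers.items()):
                rows.append(
                    {
                        "design": design,
                        "rescuer": ex_id,
                        "min_uptake": uptake,
                        "class": label,
                    }
                )
        else:
            rows.append(
                {"design": design, "rescuer": "", "min_uptake": float("nan"), "class": label}
            )
    return pd.DataFrame(rows, columns=["design", "rescuer", "min_uptake", "class"])
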