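"""Thin LP layer over scipy's HiGHS interface.

All flux balance computations in the package go through these helpers:
maximize/minimize a single reaction's flux (FBA), test feasibility, and run
flux variability analysis. Problems are built directly from the sparse
stoichiometric matrix, so no solver-specific model object is kept in sync
with the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import MetabolicNetwork

__all__ = ["LPResult", "InfeasibleModelError", "optimize_flux", "is_feasible", "fva"]

LP_TOLERANCE = 1e-9


class InfeasibleModelError(RuntimeError):
    """The model admits no steady-state flux vector under its bounds."""


@dataclass(frozen=True)
class LPResult:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective: float | None
    fluxes: np.ndarray | None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _solve(S, lb, ub, c) -> LPResult:
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 0:
        return LPResult("optimal", float(res.fun), res.x)
    if res.status == 2:
        return LPResult("infeasible", None, None)
    if res.status == 3:
        return LPResult("unbounded", None, None)
    raise RuntimeError(f"LP solver failure: {res.message}")


def optimize_flux(
    net: MetabolicNetwork,
    rxn_id: str | None = None,
    sense: str = "max",
    extra_bounds: dict[str, tuple[float, float]] | None = None,
) -> LPResult:
    """Optimize the flux of one reaction (default: the model objective).

    ``extra_bounds`` temporarily overrides bounds without copying the network;
    this is the hot path for rescue scans and brute-force enumeration.
    """
    rxn_id = rxn_id or net.objective_id
    S = net.stoichiometry()
    lb, ub = net.bounds_arrays()
    if extra_bounds:
        pos = {r.id: j for j, r in enumerate(net.reactions)}
        for rid, (lo, hi) in extra_bounds.items():
            j = pos[rid]
            lb[j], ub[j] = lo, hi
    j = net.reaction_ids.index(rxn_id)
    c = np.zeros(len(net.reactions))
    c[j] = -1.0 if sense == "max" else 1.0
    res = _solve(S, lb, ub, c)
    if res.ok:
        sign = -1.0 if sense == "max" else 1.0
        return LPResult("optimal", sign * res.objective, res.fluxes)
    return res


def is_feasible(
    net: MetabolicNetwork,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
) -> bool:
    """Whether any steady-state flux vector satisfies the bounds."""
    S = net.stoichiometry()
    lb, ub = net.bounds_arrays()
    if extra_bounds:
        pos = {r.id: j for j, r in enumerate(net.reactions)}
        for rid, (lo, hi) in extra_bounds.items():
            j = pos[rid]
            lb[j], ub[j] = lo, hi
    return _solve(S, lb, ub, np.zeros(len(net.reactions))).ok


def fva(
    net: MetabolicNetwork, rxn_ids: list[str] | None = None
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis: per-reaction (min, max) flux.

    Run at whatever optimization context the incoming bounds encode — no
    growth fraction is imposed here; callers fix or relax biomass themselves.
    """
    S = net.stoichiometry()
    lb, ub = net.bounds_arrays()
    ids = rxn_ids if rxn_ids is not None else net.reaction_ids
    pos = {r.id: j for j, r in enumerate(net.reactions)}
    if not _solve(S, lb, ub, np.zeros(len(net.reactions))).ok:
        raise InfeasibleModelError(
            f"model {net.id} is infeasible; FVA has no defined result"
        )
    out: dict[str, tuple[float, float]] = {}
    n = len(net.reactions)
    for rid in ids:
        j = pos[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo = _solve(S, lb, ub, c)
        c[j] = -1.0
        hi = _solve(S, lb, ub, c)
        if not (lo.ok and hi.ok):  # pragma: no cover - guarded by feasibility check
            raise InfeasibleModelError(f"FVA subproblem failed for {rid}")
        vmin, vmax = lo.objective, -hi.objective
        # LP round-off can invert the pair by ~1e-12; clamp to keep the
        # min<=max invariant exact.
        if vmin > vmax:
            vmin = vmax = 0.5 * (vmin + vmax)
        out[rid] = (vmin, vmax)
    return out
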