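"""Bilevel knockout search for auxotroph design.

The outer problem chooses at most K reaction knockouts; the inner LP computes
the minimum uptake of a target exchange metabolite the knockout strain needs
in order to grow at a fixed rate (``set_biomass``). The outer problem
maximizes that minimum required uptake, so optimal designs are strains that
*must* consume large amounts of the target to grow — at every feasible growth
rate, because growth is pinned rather than optimized.

Single-level reformulation
--------------------------
The inner LP (min −v_t subject to S·v = 0, bounds scaled by the knockout
binaries y, growth fixed) is dualized; strong duality lets the outer MILP
maximize the dual objective over (y, duals) subject to dual feasibility.
Products of dual variables with y are linearized with big-M terms, and a
primal feasibility copy of the flux vector excludes designs that cannot grow
even with the target available. Because big-M linearization can silently
truncate dual values, every candidate design returned by the MILP is
re-verified ("certified") by solving the inner LP directly; only certified
objectives are ever reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .core import MetabolicNetwork
from .lp import optimize_flux
from .prep import CandidateSet

__all__ = [
    "OptAuxConfig",
    "KnockoutDesign",
    "OptAuxSolution",
    "INFEASIBLE",
    "prepare_target",
    "min_target_uptake",
    "solve_optaux",
    "brute_force_oracle",
    "enumerate_alternate_designs",
]

#: Sentinel returned by :func:`min_target_uptake` when the design cannot grow
#: at ``set_biomass`` even with the target metabolite available.
INFEASIBLE = math.inf

CERTIFICATION_TOLERANCE = 1e-6
_TIE_TOLERANCE = 1e-9
_ENUMERATION_GUARD = 50_000


@dataclass(frozen=True)
class OptAuxConfig:
    """Parameters of one auxotroph-design optimization.

    set_biomass
        Growth rate (hr⁻¹) at which the inner minimum-uptake LP is solved.
    competing_metabolite_uptake_threshold
        Uptake allowance (mmol·gDW⁻¹·hr⁻¹) granted to every exchange that the
        medium leaves closed; larger values demand more specific auxotrophies.
    n_knockouts
        Maximum number of reaction knockouts K.
    target_uptake_cap
        Maximum uptake allowed for the target metabolite.
    big_M
        Linearization constant for the dual reformulation; also the cap on
        dual variables. Certification makes an undersized value detectable.
    solver_time_limit
        Wall-clock budget (s) for one MILP solve; None = no limit.
    seed
        Recorded with every solution; HiGHS is deterministic for these
        problem sizes, so the seed is bookkeeping rather than a knob.
    """

    set_biomass: float = 0.1
    competing_metabolite_uptake_threshold: float = 0.0
    n_knockouts: int = 1
    target_uptake_cap: float = 10.0
    big_M: float = 1000.0
    solver_time_limit: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.set_biomass <= 0:
            raise ValueError("set_biomass must be > 0")
        if self.competing_metabolite_uptake_threshold < 0:
            raise ValueError("competing_metabolite_uptake_threshold must be >= 0")
        if self.n_knockouts < 0:
            raise ValueError("n_knockouts must be >= 0")


@dataclass(frozen=True)
class KnockoutDesign:
    knocked_out: frozenset[str]

    def __init__(self, knocked_out=()) -> None:
        object.__setattr__(self, "knocked_out", frozenset(knocked_out))

    def sort_key(self) -> tuple:
        return (len(self.knocked_out), tuple(sorted(self.knocked_out)))


@dataclass(frozen=True)
class OptAuxSolution:
    design: KnockoutDesign
    objective: float  # certified min required uptake at set_biomass
    target_exchange: str
    config: OptAuxConfig
    solver_status: str = "optimal"


def prepare_target(
    net: MetabolicNetwork, target_exchange: str, config: OptAuxConfig
) -> MetabolicNetwork:
    """Configure the model for one OptAux target.

    Caps target uptake at ``target_uptake_cap``, opens every other exchange
    whose uptake the medium left closed to the competing-metabolite threshold,
    and fixes growth to ``set_biomass`` (lower = upper).
    """
    rxn = net.reaction(target_exchange)
    if not rxn.is_exchange:
        raise ValueError(f"{target_exchange} is not an exchange reaction")
    bounds: dict[str, tuple[float, float]] = {
        target_exchange: (-config.target_uptake_cap, rxn.upper_bound)
    }
    thr = config.competing_metabolite_uptake_threshold
    for ex in net.exchanges():
        if ex.id == target_exchange:
            continue
        if ex.lower_bound == 0.0:
            bounds[ex.id] = (-thr, ex.upper_bound)
    bounds[net.biomass_reaction_id] = (config.set_biomass, config.set_biomass)
    return net.with_bounds(bounds)


def min_target_uptake(
    net_prepared: MetabolicNetwork,
    knockouts: KnockoutDesign | None = None,
    target_exchange: str | None = None,
) -> float:
    """Inner LP: minimum uptake of the target needed to grow at set_biomass.

    Returns the :data:`INFEASIBLE` sentinel when no flux vector exists for
    the design (the strain cannot grow even with the target available);
    otherwise a non-negative uptake flux. The target defaults to the exchange
    with the most negative lower bound cap only if named — callers always
    pass it explicitly in this package.
    """
    if target_exchange is None:
        raise ValueError("target_exchange is required")
    extra = {}
    if knockouts is not None:
        for rid in knockouts.knocked_out:
            extra[rid] = (0.0, 0.0)
    res = optimize_flux(net_prepared, target_exchange, sense="max", extra_bounds=extra)
    if not res.ok:
        return INFEASIBLE
    # max v_t ⇒ min uptake = −max v_t; a strain able to secrete or ignore the
    # target needs none, hence the clamp at zero.
    return max(0.0, -res.objective)


# ---------------------------------------------------------------------------
# single-level MILP
# ---------------------------------------------------------------------------


def _build_milp(net, candidate_ids, target_exchange, config, cuts):
    """Assemble the dualized single-level MILP as scipy milp inputs.

    Variable layout: [v (n) | λ (m) | μ (n) | ν (n) | a (nc) | b (nc) | y (nc)]
    where a_j = μ_j·y_j and b_j = ν_j·y_j are the linearized products for the
    candidate reactions. Returns (c, constraints, bounds, integrality, slices).
    """
    S = net.stoichiometry().tocsc()
    m, n = S.shape
    lb, ub = net.bounds_arrays()
    rxn_pos = {rid: j for j, rid in enumerate(net.reaction_ids)}
    t = rxn_pos[target_exchange]
    cand = [rxn_pos[rid] for rid in candidate_ids]
    nc = len(cand)
    M = config.big_M

    o_v, o_l, o_mu, o_nu = 0, n, n + m, n + m + n
    o_a, o_b, o_y = o_nu + n, o_nu + n + nc, o_nu + n + 2 * nc
    nvar = o_y + nc

    # objective: maximize dual value  Σ_j (−u_j μ̂_j + l_j ν̂_j)  where the
    # hatted variables are a/b for candidates and μ/ν otherwise, plus a tiny
    # bonus for keeping reactions (prefer fewer knockouts among ties).
    # c below is the scipy MINIMIZE vector, i.e. the negated dual objective.
    c = np.zeros(nvar)
    cand_set = set(cand)
    for j in range(n):
        if j in cand_set:
            continue
        c[o_mu + j] = ub[j]
        c[o_nu + j] = -lb[j]
    for k, j in enumerate(cand):
        c[o_a + k] = ub[j]
        c[o_b + k] = -lb[j]
    c[o_y : o_y + nc] -= 1e-6  # scipy minimizes; negative cost favors y_j = 1

    rows_eq = []  # (coeff dict, lo, hi)

    # dual feasibility: S^T λ + μ − ν = −c_inner, with c_inner = −e_t
    ST = S.transpose().tocsr()
    for j in range(n):
        coeffs = {}
        start, end = ST.indptr[j], ST.indptr[j + 1]
        for idx in range(start, end):
            coeffs[o_l + ST.indices[idx]] = ST.data[idx]
        coeffs[o_mu + j] = 1.0
        coeffs[o_nu + j] = -1.0
        rhs = 1.0 if j == t else 0.0
        rows_eq.append((coeffs, rhs, rhs))

    # primal feasibility copy: S v = 0
    Scsr = S.tocsr()
    for i in range(m):
        coeffs = {}
        start, end = Scsr.indptr[i], Scsr.indptr[i + 1]
        for idx in range(start, end):
            coeffs[o_v + Scsr.indices[idx]] = Scsr.data[idx]
        rows_eq.append((coeffs, 0.0, 0.0))

    rows_ineq = []
    for k, j in enumerate(cand):
        y = o_y + k
        # knockout coupling on the primal copy: l_j y ≤ v_j ≤ u_j y
        rows_ineq.append(({o_v + j: 1.0, y: -ub[j]}, -np.inf, 0.0))
        rows_ineq.append(({o_v + j: -1.0, y: lb[j]}, -np.inf, 0.0))
        # a = μ·y linearization
        rows_ineq.append(({o_a + k: 1.0, y: -M}, -np.inf, 0.0))
        rows_ineq.append(({o_a + k: 1.0, o_mu + j: -1.0}, -np.inf, 0.0))
        rows_ineq.append(({o_mu + j: 1.0, o_a + k: -1.0, y: M}, -np.inf, M))
        # b = ν·y linearization
        rows_ineq.append(({o_b + k: 1.0, y: -M}, -np.inf, 0.0))
        rows_ineq.append(({o_b + k: 1.0, o_nu + j: -1.0}, -np.inf, 0.0))
        rows_ineq.append(({o_nu + j: 1.0, o_b + k: -1.0, y: M}, -np.inf, M))

    # knockout budget: Σ y ≥ nc − K
    rows_ineq.append(
        ({o_y + k: 1.0 for k in range(nc)}, nc - config.n_knockouts, np.inf)
    )

    # integer cuts: forbid previously returned knockout patterns
    for knocked in cuts:
        coeffs = {}
        rhs_shift = 0.0
        for k, rid in enumerate(candidate_ids):
            if rid in knocked:
                coeffs[o_y + k] = 1.0
            else:
                coeffs[o_y + k] = -1.0
                rhs_shift += 1.0
        # Σ_{j∈D} y_j + Σ_{j∉D} (1−y_j) ≥ 1
        rows_ineq.append((coeffs, 1.0 - rhs_shift, np.inf))

    def to_constraint(rows):
        data, ri, ci, lo, hi = [], [], [], [], []
        for r, (coeffs, l, h) in enumerate(rows):
            for col, val in coeffs.items():
                ri.append(r)
                ci.append(col)
                data.append(val)
            lo.append(l)
            hi.append(h)
        A = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), nvar))
        return LinearConstraint(A, lo, hi)

    var_lo = np.full(nvar, -np.inf)
    var_hi = np.full(nvar, np.inf)
    var_lo[o_v : o_v + n] = lb
    var_hi[o_v : o_v + n] = ub
    var_lo[o_mu : o_mu + n] = 0.0
    var_hi[o_mu : o_mu + n] = M
    var_lo[o_nu : o_nu + n] = 0.0
    var_hi[o_nu : o_nu + n] = M
    var_lo[o_a : o_b + nc] = 0.0
    var_hi[o_a : o_b + nc] = M
    var_lo[o_y : o_y + nc] = 0.0
    var_hi[o_y : o_y + nc] = 1.0

    integrality = np.zeros(nvar)
    integrality[o_y : o_y + nc] = 1

    constraints = [to_constraint(rows_eq + rows_ineq)]
    return c, constraints, Bounds(var_lo, var_hi), integrality, (o_y, nc)


def _solve_milp_once(net, candidate_ids, target_exchange, config, cuts):
    c, constraints, bounds, integrality, (o_y, nc) = _build_milp(
        net, candidate_ids, target_exchange, config, cuts
    )
    options = {}
    if config.solver_time_limit is not None:
        options["time_limit"] = config.solver_time_limit
    res = milp(
        c,
        constraints=constraints,
        bounds=bounds,
        integrality=integrality,
        options=options,
    )
    if res.x is None:
        return None, None, res.status
    y = res.x[o_y : o_y + nc]
    knocked = frozenset(
        rid for rid, yk in zip(candidate_ids, y) if yk < 0.5
    )
    claim = -res.fun - 1e-6 * float(np.round(y).sum())
    status = "time_limit" if res.status == 1 else "optimal"
    return knocked, claim, status


def _prune_design(net, target_exchange, knocked: frozenset, objective: float):
    """Drop knockouts (in sorted id order) that do not lower the objective."""
    kept = sorted(knocked)
    for rid in sorted(knocked):
        trial = [r for r in kept if r != rid]
        val = min_target_uptake(net, KnockoutDesign(trial), target_exchange)
        if val is not INFEASIBLE and val >= objective - _TIE_TOLERANCE:
            kept = trial
    return frozenset(kept)


def solve_optaux(
    net_prepared: MetabolicNetwork,
    candidates: CandidateSet,
    target_exchange: str,
    config: OptAuxConfig,
    _extra_cuts: tuple = (),
) -> OptAuxSolution:
    """Solve the bilevel knockout problem for one target.

    Every MILP incumbent is certified by re-solving the inner LP on the
    returned design; if the big-M claim and the certified value disagree, the
    design is cut and the search continues, so the reported objective is
    always the true minimum required uptake of the returned design.
    """
    candidate_ids = [
        rid for rid in candidates.knockout_candidates if net_prepared.has_reaction(rid)
    ]
    if config.n_knockouts == 0 or not candidate_ids:
        wt = min_target_uptake(net_prepared, KnockoutDesign(), target_exchange)
        obj = 0.0 if wt is INFEASIBLE else wt
        return OptAuxSolution(KnockoutDesign(), obj, target_exchange, config, "optimal")

    cuts: list[frozenset] = list(_extra_cuts)
    best_design: frozenset | None = None
    best_obj = -math.inf
    status = "optimal"
    for _ in range(25):
        knocked, claim, st = _solve_milp_once(
            net_prepared, candidate_ids, target_exchange, config, cuts
        )
        if knocked is None:
            break
        status = st
        cert = min_target_uptake(
            net_prepared, KnockoutDesign(knocked), target_exchange
        )
        if cert is not INFEASIBLE and cert > best_obj:
            best_obj, best_design = cert, knocked
        if cert is not INFEASIBLE and abs(cert - claim) <= CERTIFICATION_TOLERANCE:
            break
        # claim uncertified (big-M slack or an infeasible-growth artifact):
        # exclude this pattern and keep searching
        cuts.append(knocked)
        if claim is not None and claim <= best_obj + CERTIFICATION_TOLERANCE:
            break
    if best_design is None or best_obj <= _TIE_TOLERANCE:
        wt = min_target_uptake(net_prepared, KnockoutDesign(), target_exchange)
        obj = 0.0 if wt is INFEASIBLE else wt
        return OptAuxSolution(KnockoutDesign(), obj, target_exchange, config, status)
    pruned = _prune_design(net_prepared, target_exchange, best_design, best_obj)
    return OptAuxSolution(
        KnockoutDesign(pruned), best_obj, target_exchange, config, status
    )


def brute_force_oracle(
    net_prepared: MetabolicNetwork,
    candidates: CandidateSet,
    target_exchange: str,
    config: OptAuxConfig,
) -> OptAuxSolution:
    """Exhaustive argmax over all knockout subsets of size ≤ K.

    Independent of the MILP path: each subset is evaluated with the inner LP
    directly. Ties break toward fewer knockouts, then the lexicographically
    smallest id set. Refuses to enumerate more than 50,000 subsets.
    """
    candidate_ids = sorted(
        rid for rid in candidates.knockout_candidates if net_prepared.has_reaction(rid)
    )
    total = sum(
        math.comb(len(candidate_ids), k)
        for k in range(0, min(config.n_knockouts, len(candidate_ids)) + 1)
    )
    if total > _ENUMERATION_GUARD:
        raise ValueError(
            f"{total} subsets exceed the enumeration guard ({_ENUMERATION_GUARD})"
        )
    best_obj = -math.inf
    best_key = None
    best_design: tuple = ()
    for k in range(0, min(config.n_knockouts, len(candidate_ids)) + 1):
        for combo in itertools.combinations(candidate_ids, k):
            val = min_target_uptake(
                net_prepared, KnockoutDesign(combo), target_exchange
            )
            if val is INFEASIBLE:
                continue
            key = (-val, len(combo), combo)
            if best_key is None or (
                val > best_obj + _TIE_TOLERANCE
                or (abs(val - best_obj) <= _TIE_TOLERANCE and key < best_key)
            ):
                best_obj, best_key, best_design = val, key, combo
    if best_key is None:
        return OptAuxSolution(
            KnockoutDesign(), 0.0, target_exchange, config, "infeasible"
        )
    return OptAuxSolution(
        KnockoutDesign(best_design), best_obj, target_exchange, config, "optimal"
    )


def enumerate_alternate_designs(
    net_prepared: MetabolicNetwork,
    candidates: CandidateSet,
    target_exchange: str,
    config: OptAuxConfig,
    max_solutions: int = 10,
    rel_tolerance: float = 1e-4,
) -> list[OptAuxSolution]:
    """Collect alternate optimal knockout sets via integer cuts.

    Re-solves with each returned knockout pattern forbidden until the
    certified objective drops below ``(1 − rel_tolerance) ×`` the best, or
    ``max_solutions`` designs have been collected. Returns an empty list when
    the best objective is 0 (no auxotrophy exists for the target).
    """
    first = solve_optaux(net_prepared, candidates, target_exchange, config)
    if first.objective <= _TIE_TOLERANCE:
        return []
    solutions = [first]
    cuts = [first.design.knocked_out]
    while len(solutions) < max_solutions:
        nxt = solve_optaux(
            net_prepared, candidates, target_exchange, config, _extra_cuts=tuple(cuts)
        )
        if (
            nxt.objective < (1.0 - rel_tolerance) * first.objective
            or nxt.design.knocked_out in cuts
        ):
            break
        solutions.append(nxt)
        cuts.append(nxt.design.knocked_out)
    return solutions
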