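"""Bilevel knockout search: inner LP, MILP vs brute force, monotonicity."""

import math

import pytest

from auxodesign import (
    INFEASIBLE,
    KnockoutDesign,
    OptAuxConfig,
    apply_medium,
    brute_force_oracle,
    enumerate_alternate_designs,
    filter_knockout_candidates,
    min_target_uptake,
    prepare_target,
    reduce_by_fva,
    solve_optaux,
)
from auxodesign.synthdata import ToyNetworkSpec, make_toy_network

GROWTH = 0.1


def pipeline(net, truth, target, config):
    """medium → target prep → FVA reduction → candidate filter."""
    netm = apply_medium(net, truth.medium)
    prepared = prepare_target(netm, target, config)
    reduced = reduce_by_fva(prepared)
    return reduced, filter_knockout_candidates(reduced)


class TestPrepareTarget:
    def test_biomass_fixed(self, toy_on_medium):
        net, truth = toy_on_medium
        prep = prepare_target(net, truth.target_exchanges[0], OptAuxConfig())
        bio = prep.reaction(prep.biomass_reaction_id)
        assert (bio.lower_bound, bio.upper_bound) == (GROWTH, GROWTH)

    def test_target_capped_at_ten(self, toy_on_medium):
        net, truth = toy_on_medium
        target = truth.target_exchanges[0]
        prep = prepare_target(net, target, OptAuxConfig())
        assert prep.reaction(target).lower_bound == -10.0

    @pytest.mark.parametrize("threshold", [0.0, 0.01, 0.1, 2.0])
    def test_competing_exchanges_opened_to_threshold(self, toy_on_medium, threshold):
        net, truth = toy_on_medium
        target = truth.target_exchanges[0]
        config = OptAuxConfig(competing_metabolite_uptake_threshold=threshold)
        prep = prepare_target(net, target, config)
        for ex in prep.exchanges():
            if ex.id == target:
                continue
            if ex.id in truth.medium:
                assert ex.lower_bound == -truth.medium.uptake_bounds[ex.id]
            else:
                assert ex.lower_bound == -threshold

    def test_non_exchange_target_rejected(self, toy_on_medium):
        net, truth = toy_on_medium
        with pytest.raises(ValueError, match="not an exchange"):
            prepare_target(net, truth.routes[0][0], OptAuxConfig())


class TestMinTargetUptake:
    def test_wild_type_needs_nothing(self, toy_on_medium):
        net, truth = toy_on_medium
        target = truth.target_exchanges[1]
        prep = prepare_target(net, target, OptAuxConfig())
        assert min_target_uptake(prep, KnockoutDesign(), target) == pytest.approx(0.0)

    def test_single_route_knockout_mass_balance(self, toy_on_medium):
        """Starving precursor p makes its uptake = biomass coefficient × μ."""
        net, truth = toy_on_medium
        target = truth.target_exchanges[2]
        prep = prepare_target(net, target, OptAuxConfig())
        design = KnockoutDesign(truth.routes[2])
        value = min_target_uptake(prep, design, target)
        assert value == pytest.approx(truth.biomass_stoich[2] * GROWTH, abs=1e-9)

    def test_infeasible_design_is_sentinel(self, toy_on_medium):
        """Starving a different precursor than the target is unsurvivable."""
        net, truth = toy_on_medium
        target = truth.target_exchanges[2]
        prep = prepare_target(net, target, OptAuxConfig())
        design = KnockoutDesign(truth.routes[1])  # p1 starved, p1 closed
        assert min_target_uptake(prep, design, target) is INFEASIBLE


class TestSolveOptAux:
    def test_matches_oracle_single_knockout(self, toy):
        net, truth = toy
        config = OptAuxConfig(n_knockouts=1)
        for i, target in enumerate(truth.target_exchanges):
            reduced, cands = pipeline(net, truth, target, config)
            sol = solve_optaux(reduced, cands, target, config)
            oracle = brute_force_oracle(reduced, cands, target, config)
            assert sol.objective == pytest.approx(oracle.objective, abs=1e-6)
            assert sol.objective == pytest.approx(
                truth.optimal_uptake(i, 1, GROWTH), abs=1e-6
            )

    def test_zero_knockouts_reports_wild_type(self, toy):
        net, truth = toy
        config = OptAuxConfig(n_knockouts=0)
        target = truth.target_exchanges[0]
        reduced, cands = pipeline(net, truth, target, config)
        sol = solve_optaux(reduced, cands, target, config)
        assert sol.design.knocked_out == frozenset()
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_certification_invariant(self, toy):
        """Returned objectives equal the inner LP recomputed on the design."""
        net, truth = toy
        config = OptAuxConfig(n_knockouts=2, competing_metabolite_uptake_threshold=0.1)
        for target in truth.target_exchanges:
            reduced, cands = pipeline(net, truth, target, config)
            sol = solve_optaux(reduced, cands, target, config)
            recomputed = min_target_uptake(reduced, sol.design, target)
            recomputed = 0.0 if recomputed is INFEASIBLE else recomputed
            assert sol.objective == pytest.approx(recomputed, abs=1e-6)

    def test_objective_bounded_by_cap(self, toy):
        net, truth = toy
        config = OptAuxConfig(n_knockouts=2)
        target = truth.target_exchanges[1]
        reduced, cands = pipeline(net, truth, target, config)
        sol = solve_optaux(reduced, cands, target, config)
        assert 0.0 <= sol.objective <= config.target_uptake_cap

    def test_threshold_monotonicity(self, toy):
        """Optimal objective is non-increasing in the competing threshold."""
        net, truth = toy
        previous = math.inf
        target = truth.target_exchanges[0]  # p0 has the alternative substrate
        for threshold in (0.0, 0.01, 0.1, 2.0):
            config = OptAuxConfig(
                n_knockouts=1, competing_metabolite_uptake_threshold=threshold
            )
            reduced, cands = pipeline(net, truth, target, config)
            sol = solve_optaux(reduced, cands, target, config)
            assert sol.objective <= previous + 1e-9
            previous = sol.objective

    def test_knockout_monotonicity(self, toy):
        """Optimal objective is non-decreasing in the knockout budget K."""
        net, truth = toy
        target = truth.target_exchanges[1]  # two isozymes: needs K=2
        previous = -math.inf
        values = []
        for k in (0, 1, 2):
            config = OptAuxConfig(n_knockouts=k)
            reduced, cands = pipeline(net, truth, target, config)
            sol = solve_optaux(reduced, cands, target, config)
            assert sol.objective >= previous - 1e-9
            previous = sol.objective
            values.append(sol.objective)
        # isozyme redundancy: single knockouts achieve nothing, double does
        assert values[1] == pytest.approx(0.0, abs=1e-9)
        assert values[2] == pytest.approx(
            truth.biomass_stoich[1] * GROWTH, abs=1e-6
        )


class TestBruteForceOracle:
    def test_deterministic_tie_break(self, toy):
        """Isozyme knockouts tie at 0; the lexicographically first empty set wins."""
        net, truth = toy
        config = OptAuxConfig(n_knockouts=1)
        target = truth.target_exchanges[1]
        reduced, cands = pipeline(net, truth, target, config)
        oracle = brute_force_oracle(reduced, cands, target, config)
        # all single KOs of isozymes give 0, as does no knockout: prefer fewer
        assert oracle.design.knocked_out == frozenset()

    def test_enumeration_guard(self, toy, monkeypatch):
        import auxodesign.optaux as mod

        net, truth = toy
        config = OptAuxConfig(n_knockouts=2)
        target = truth.target_exchanges[0]
        reduced, cands = pipeline(net, truth, target, config)
        monkeypatch.setattr(mod, "_ENUMERATION_GUARD", 3)
        with pytest.raises(ValueError, match="guard"):
            brute_force_oracle(reduced, cands, target, config)


class TestAlternateDesigns:
    def test_isozyme_pair_gives_two_designs(self):
        """A duplicated route yields two distinct optimal single knockouts."""
        net, truth = make_toy_network(
            ToyNetworkSpec(
                seed=3,
                n_precursors=2,
                biomass_stoich=(2.0, 1.0),
                isozymes=(1, 1),
                include_decoys=False,
            )
        )
        # add a duplicate of p0's sole route so two optima exist
        dup = net.reaction(truth.routes[0][0]).copy()
        dup.id = dup.id + "_dup"
        net = type(net)(
            net.reactions + [dup], net.metabolites, net.biomass_reaction_id
        )
        config = OptAuxConfig(n_knockouts=2)
        target = truth.target_exchanges[0]
        netm = apply_medium(net, truth.medium)
        prepared = prepare_target(netm, target, config)
        reduced = reduce_by_fva(prepared)
        cands = filter_knockout_candidates(reduced)
        solutions = enumerate_alternate_designs(
            reduced, cands, target, config, max_solutions=5
        )
        assert len(solutions) == 1
        # both copies must go: the only optimal design is the double knockout
        assert solutions[0].design.knocked_out == frozenset(
            {truth.routes[0][0], truth.routes[0][0] + "_dup"}
        )

    def test_two_single_ko_optima_enumerated(self, toy):
        """p0 at threshold 2 (> b0·μ): SYN and CONV knockouts both score b0·μ...

        At threshold 2 the alternative substrate fully substitutes, so the
        only positive-objective design must cut both routes; with K=2 there is
        exactly one such design and enumeration returns it alone.
        """
        net, truth = toy
        config = OptAuxConfig(n_knockouts=2, competing_metabolite_uptake_threshold=2.0)
        target = truth.target_exchanges[0]
        netm = apply_medium(net, truth.medium)
        prepared = prepare_target(netm, target, config)
        reduced = reduce_by_fva(prepared)
        cands = filter_knockout_candidates(reduced)
        solutions = enumerate_alternate_designs(
            reduced, cands, target, config, max_solutions=5
        )
        assert len(solutions) == 1
        assert solutions[0].design.knocked_out == frozenset(
            {truth.routes[0][0], truth.alt_route}
        )

    def test_max_solutions_one(self, toy):
        net, truth = toy
        config = OptAuxConfig(n_knockouts=1)
        target = truth.target_exchanges[0]
        reduced, cands = pipeline(net, truth, target, config)
        sols = enumerate_alternate_designs(
            reduced, cands, target, config, max_solutions=1
        )
        single = solve_optaux(reduced, cands, target, config)
        assert len(sols) == 1
        assert sols[0].objective == pytest.approx(single.objective, abs=1e-9)

    def test_zero_objective_returns_empty(self, toy):
        net, truth = toy
        config = OptAuxConfig(n_knockouts=1)
        target = truth.target_exchanges[1]  # isozymes: K=1 cannot starve it
        reduced, cands = pipeline(net, truth, target, config)
        assert enumerate_alternate_designs(reduced, cands, target, config) == []
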