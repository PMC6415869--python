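# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the numerical choices, and what the synthetic test
data does and does not establish.

## Flux balance setting

All constraint-based computations share one representation: a stoichiometric
matrix S (metabolite × reaction), flux bounds lb ≤ v ≤ ub in
mmol·gDW⁻¹·hr⁻¹, and the steady-state constraint S·v = 0. Exchange reactions
follow the export-positive convention (one metabolite, coefficient −1), so
uptake is u = −v and is reported non-negative everywhere in the public API.
Exchanges are detected structurally — a reaction touching exactly one
metabolite — because compartment naming is unreliable across model dialects;
when the source format explicitly classifies boundary reactions (as
cobra/SBML do), that classification wins, which keeps cytosolic demand and
sink drains (e.g. iJO1366's six `DM_*` reactions) out of the exchange set.
This distinction is what makes the carbon-target count on iJO1366 come out
at 285 rather than 291.

A medium is a map {exchange id → maximum uptake}; applying it sets the
listed exchanges' lower bounds to −value and closes every other exchange.
The packaged `glucose_M9.yaml` reproduces the iJO1366 default minimal medium
with oxygen uptake capped at 20 mmol·gDW⁻¹·hr⁻¹. LPs are solved with HiGHS
through scipy (`linprog`); the solver is deterministic at these problem
sizes.

## Auxotroph design (bilevel knockout search)

**Problem.** Choose at most K reaction knockouts maximizing the minimum
uptake of a target exchange metabolite required to grow at a fixed rate
μ\* (`set_biomass`, default 0.1 hr⁻¹). Pinning growth — rather than
embedding an inner growth maximization — makes the target requirement hold
at every feasible growth rate, which is the property a co-culture founder
strain needs. Key parameters:

| parameter | default | meaning |
|---|---|---|
| `set_biomass` | 0.1 hr⁻¹ | growth rate at which the inner LP is solved |
| `competing_metabolite_uptake_threshold` | 0 | uptake allowance on every medium-closed exchange; sweeping {0, 0.01, 0.1, 2} trades solution specificity |
| `target_uptake_cap` | 10 | maximum target uptake, bounds the objective |
| `n_knockouts` (K) | 1 | knockout budget |
| `big_M` | 1000 | dual-variable cap in the linearization |

**Preparation.** For each target: cap its uptake at 10, open all other
closed exchanges to the competing threshold, fix biomass bounds to μ\*.
The model is then reduced by flux variability analysis — bounds clamped to
the per-reaction [min, max] flux, zero-range reactions (|flux| < 1e-6)
deleted. FVA runs with the biomass lower bound relaxed to 0 so the reduction
never excludes the low-growth states the design problem lives in; the
competing threshold is opened *before* FVA so reduction cannot prune the
very uptake routes the threshold grants. Knockout candidates then exclude:
user-supplied model false positives, user-supplied rich-media-essential
reactions, ten blocklisted subsystems (envelope/murein/LPS biosynthesis,
transport, exchanges, tRNA charging), any reaction touching a metabolite
with more than 10 carbons, and spontaneous reactions. The essentiality and
false-positive lists are inputs (plain-text reaction ids), not recomputed.

**Reformulation.** The inner LP (min −v_t subject to S·v = 0, knockout-scaled
bounds, fixed growth) is dualized; strong duality turns max-min into a single
maximization over (y, duals) subject to dual feasibility, with the dual ×
binary products linearized via big-M terms and dual variables capped at
big_M. A primal feasibility copy with the same knockout coupling excludes
designs that cannot grow at μ\* even with the target open (such a strain is
not an auxotroph, it is dead). The MILP (HiGHS through `scipy.optimize.milp`)
carries a 1e-6 preference for keeping reactions, so objective-tied solutions
favor fewer knockouts.

**Certification.** Big-M truncation can make the MILP claim a value the
design does not actually achieve. Every incumbent is therefore re-verified
by solving the inner LP on the returned knockout set; on disagreement beyond
1e-6 the pattern is excluded with an integer cut and the search continues
(at most 25 rounds, never observed to need more than one on the test
networks). The reported objective is always the certified inner-LP value. A
greedy post-pass drops knockouts (in sorted id order) that do not lower the
certified objective. Alternate optima are enumerated by re-solving under
integer cuts until the certified objective falls below (1 − 1e-4) × best.

An exhaustive oracle (`brute_force_oracle`) evaluates the inner LP on every
subset of size ≤ K (guard: 50,000 subsets), with a deterministic tie-break
(fewer knockouts, then lexicographic ids). It shares no code with the MILP
path beyond the inner LP and anchors the equivalence tests.

## Rescue profiles and design classes

A design is auxotrophic if growth at the test rate is infeasible on the base
medium. Its rescuers are found by opening each carbon exchange the medium
leaves closed, one at a time, up to a supplement cap of 10 mmol·gDW⁻¹·hr⁻¹
(mirroring the target cap; the profile values are far below it in practice),
and recording the minimum uptake that sustains growth. Classification is a
pure function of the rescuer count: 1 → EBC-specific, 2–4 →
EBC-semi-specific, ≥ 5 → MSE. An auxotroph with zero single-metabolite
rescuers raises a distinguished error rather than receiving a class — such
designs need combination feeding, which is out of scope. "Unique
auxotrophies" are defined by identical rescuer *sets* (uptake values may
differ), which is the grouping a co-culture designer cares about: two
designs with the same rescuer set occupy the same nutritional niche.

Note on published averages: for the iJO1366 TCA triple knockout
(FUM+PPC+MALS) the widely quoted 0.40 mmol·gDW⁻¹·hr⁻¹ average is over the
four headline rescuers (citrate, L-malate, 2-oxoglutarate, L-asparagine);
the full 18-rescuer profile averages 0.383. The GLUDy+GLUSy 0.62 average is
over its full 19-rescuer profile. The acceptance checks compute both the
way they were originally reported.

## Community model

Two strains (with their knockouts applied, ids prefixed `S1_`/`S2_`) share
an extracellular compartment. Each strain-level exchange becomes a link
reaction `met_strain → X · met_shared` where X is the strain's dry-weight
fraction: one unit of strain-level flux (per gDW strain) delivers X
community-level units (per gDW community), which is the correct mass
balance for a mixed culture. Cross-feed policy: secretion into the pool is
always open; uptake from the pool is open only for metabolites in the
allowed cross-feed set (by default, everything that rescues either partner)
or supplied by the shared medium. The shared medium is applied at
shared-compartment exchanges (e.g. glucose ≤ 5 mmol·gDW_community⁻¹·hr⁻¹).
A balancing pseudo-metabolite row forces the two biomass fluxes equal —
serial-passage co-cultures that persist must grow at one average rate — and
community growth is that common rate, maximized by LP.

Composition is a parameter, not a variable: the sweep fixes X on a grid
(default ten points, 0.05–0.95), maximizes growth at each, appends X ∈
{0, 1} with growth 0 (an auxotroph monoculture cannot grow), and reports
the argmax plus the ≥ 95%-of-max set. An unbounded LP raises an instructive
error: metabolism-only models need a substrate cap, since nothing else
limits growth. `restrict_crossfeed` closes all cross-feed uptake except one
named metabolite (plus any reciprocal metabolites passed in `also_keep`),
for probing which single compound can carry the syntrophy.

Proteome-limited behavior (models of metabolism and expression, enzyme
efficiency sweeps) is deliberately out of scope; in plain FBA with
unbounded transporters, cross-feeding is free and the growth-vs-composition
curve is flat — composition effects appear only once transport or substrate
capacities bind, which the examples demonstrate by capping transporters.
If a metabolite must be cross-fed but has no export path in a strain,
`add_export_route` patches in a reversible diffusion route plus a closed
exchange; this is left explicit rather than automatic because inferring the
right compartment chain in an arbitrary model is guesswork.

## Sequencing analytics

**Abundance, mutation-based.** Each strain carries one or two characteristic
("barcode") mutations; the strain's raw abundance is the mean of its
observed marker frequencies. Markers missing from a sample are dropped (a
strain with one detected marker falls back to that frequency alone); a
strain with no detected marker is an error, not a zero. The two raw values
are normalized to sum to exactly 1 (the second strain gets the complement,
avoiding float residue).

**Abundance, coverage-based.** Reads over a strain's *deleted* ORF can only
come from the partner, so mean ORF depth / genome-wide mean depth estimates
the partner's abundance; two deleted genes are averaged. The genome-wide
mean includes the depleted ORFs themselves — on a multi-Mbp genome the bias
is negligible and cancels under normalization.

**Duplication calling.** Reference depth statistic is configurable:
10%-trimmed mean of per-base depth (default — robust to the duplications
being called), median, or the mean of the LOWESS-fitted profile
(`fit_mean`). A gene is flagged when strictly more than 80% of its ORF
bases lie strictly above 1.25 × reference (both comparisons strict, both
configurable); genes already duplicated in the starting strains are
removed; flagged genes group along the genome, a new group starting when
more than five genes intervene. Group multiplicity is mean group-ORF depth
over the reference. Coordinates are 1-based inclusive internally; BED input
is converted at the boundary. Strand is ignored (depth is strand-summed).

**Smoothing.** The depth vector is split into 50,000 near-equal segments
(reduced with a warning for shorter genomes), segment means are taken, and
LOWESS (statsmodels) is applied over segment index with a 0.5% window and
zero robustness reweightings.

## Synthetic data: what it emulates, what it does not

The toy-network generator builds a glucose hub with per-precursor synthesis
routes (optionally duplicated as isozymes, optionally with a closed
alternative substrate), transporters and closed exchanges per precursor,
and a biomass reaction consuming each precursor with known coefficients.
Every quantity of interest is analytic: starving precursor *p* makes its
exchange the rescuer with minimum uptake = coefficient × growth rate, and
the optimal design objective for any (target, K, threshold) follows by
enumeration over precursors. Transport and exchange reactions carry
blocklisted subsystems so the candidate pool is exactly the synthesis
routes. Decoy reactions (a dead-end 12-carbon product, a spontaneous leak)
exercise FVA pruning and the candidate filter.

The sequencing generator tiles genes over a 100 kbp genome (100 genes —
short enough that the 50,000-segment smoother exercises its fallback),
draws per-base depth as Poisson (or gamma-Poisson for overdispersion)
around mean 100×, multiplies planted duplication spans, and depletes each
strain's knocked-out ORF by that strain's fraction. Marker frequencies are
binomial at a stated read depth. All generators are pure functions of
(spec, seed).

What passing these tests shows: the algorithms implement their definitions
correctly, the MILP agrees with exhaustive search, the estimators are
unbiased at the modeled noise. What they do not show: robustness to
GC-content coverage bias, mapping artifacts, strain-shared duplications, or
real media/transporter uncertainty in genome-scale models — real data keep
all of those.

## Problem sizes and tolerances

LP tolerance is HiGHS default (~1e-9); zero-flux threshold for FVA deletion
is 1e-6 mmol·gDW⁻¹·hr⁻¹; MILP certification tolerance 1e-6; alternate-optima
relative tolerance 1e-4. The test battery uses 20 toy networks (2–5
precursors, K ≤ 2, thresholds {0, 0.01, 0.1, 2}) for MILP/oracle
equivalence, 9 strain fractions for abundance recovery, and 3 seeds for
duplication recovery; the genome-scale checks run iJO1366 (2583 reactions)
with ~280 LPs per rescue profile. The full all-targets design sweep over
iJO1366 (hundreds of MILPs) is a batch job a user runs target-by-target via
the CLI, not part of the routine suite.
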