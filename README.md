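# auxodesign

Model-driven design and analysis of metabolically coupled *E. coli*
co-cultures. The package is aimed at researchers who engineer synthetic
microbial communities from auxotrophic mutants: it designs the auxotrophs on
a genome-scale metabolic model, predicts which metabolites rescue them and
how strongly they must be fed, models the resulting two-strain community at
any strain ratio, and analyzes time-course sequencing of the evolving
co-culture (strain abundances and genome duplications).

## The optimization at the core

Given a stoichiometric model (S, v, lb, ub), a fixed growth rate μ\*
(`set_biomass`), and a target exchange reaction *t*, the design problem is a
bilevel MILP over knockout indicators y ∈ {0,1}ⁿ (yⱼ = 0 ⇔ reaction *j*
knocked out):

```
max_y   min_v  u_t                      u_t = −v_t  (uptake of the target)
s.t.    S·v = 0
        yⱼ·lbⱼ ≤ vⱼ ≤ yⱼ·ubⱼ           knockouts force vⱼ = 0
        v_biomass = μ*                  growth pinned, not optimized
        u_t ≤ 10                        target uptake cap
        Σⱼ (1 − yⱼ) ≤ K                 at most K knockouts
```

Every exchange the medium leaves closed is opened to a small
*competing-metabolite uptake threshold*, so the search can demand designs
that stay auxotrophic even when other nutrients are around. Because growth is
pinned rather than maximized, optimal designs require the target at **every**
feasible growth rate, not just near μmax. The inner LP is dualized
(strong duality + big-M linearization) to a single-level MILP solved with
HiGHS; every returned design is re-certified by solving the inner LP
directly, so reported objectives never rest on the big-M reformulation alone.

Downstream, designs are characterized by their *rescue profile* (the set of
metabolites that individually restore growth, each with its minimum required
uptake) and classified: one rescuer = specific essential-biomass-component
(EBC) auxotroph, two to four = semi-specific EBC, five or more = major
subsystem elimination (MSE). Two designs form a community model with one
compartment per strain and a shared extracellular compartment; strain
boundary fluxes are scaled by the strain's dry-weight fraction X so shared
fluxes are per gDW of community, and both strains are constrained to one
common growth rate. Sequencing analytics estimate strain abundances from
characteristic-mutation frequencies and from read depth over knocked-out
ORFs, and call genome duplications with a 1.25×-coverage / 80%-of-ORF /
5-gene-gap rule.

## Worked example

Design a single-knockout auxotroph on a generated toy network and verify the
answer against exhaustive enumeration:

```
$ python examples/01_design_auxotroph.py
target exchange        : EX_p0_e
knockout candidates    : ['SYN_p0', 'SYN_p1', 'SYN_p2']
MILP design            : ['SYN_p0']
min required uptake    : 0.1780 mmol/gDW/hr
brute-force optimum    : 0.1780 (agreement check)
```

The MILP knocks out p0's only synthesis route; mass balance then forces the
strain to import p0 at (biomass coefficient 1.78) × (growth rate 0.1 hr⁻¹) =
0.178 mmol·gDW⁻¹·hr⁻¹ — exactly the certified objective, and exactly what
brute-force enumeration finds. The other scripts in `examples/` walk through
rescue characterization, the community composition sweep (a symmetric
cross-feeding pair peaks at a 50:50 ratio), both strain-abundance estimators
on a planted 70/30 mixture, duplication calling on a planted 2× event, and
the genome-scale numbers below.

On iJO1366 (`examples/06_ijo1366_numbers.py`): 285 carbon-metabolite uptake
targets; the ASNS1+ASNS2 (asparagine synthetase) double knockout needs
0.0241 mmol·gDW⁻¹·hr⁻¹ of L-asparagine to grow at 0.1 hr⁻¹; the DHORTS,
GLUDy+GLUSy, and CS knockouts are rescued by 20, 19, and 14 individual
metabolites respectively.

## Command line

A thin CLI wraps the library:

```
auxodesign design --model m.json --target EX_asn__L_e --knockouts 2 \
    --threshold 2 --set-biomass 0.1 --out solutions/
auxodesign characterize --model m.json --knockouts DHORTS --medium m9.yaml
auxodesign community-sweep --model m.json --ko-a HISTD --ko-b GLUDy,GLUSy \
    --crossfeed his__L_e,glu__L_e --glucose 5
auxodesign dupcall --coverage cov.tsv --genes genes.bed
auxodesign abundance --mutations muts.csv --markers "A=mk1;mk2,B=mk3"
auxodesign fixtures --kind toy-network --seed 1
```

Every run writes its outputs as sorted TSV plus a JSON manifest (config,
seed, version, wall time).

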