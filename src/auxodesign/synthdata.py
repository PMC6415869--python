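"""Deterministic generators for test inputs with known ground truth.

Two families:

* toy metabolic networks whose auxotrophy structure is known by construction
  (each biomass precursor has one or more synthesis routes; deleting all
  routes of precursor *p* makes the exchange of *p* the unique rescuer, with
  a minimum uptake that follows from linear mass balance: biomass coefficient
  × growth rate);
* synthetic sequencing data — coverage tracks with Poisson or
  negative-binomial noise, planted duplications, knockout-gene depletion
  encoding true strain fractions, and characteristic-mutation frequency
  tables with binomial sampling noise.

Everything is a pure function of (spec, seed); identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_BOUND, Medium, MetabolicNetwork, Metabolite, Reaction
from .cocultureseq import CoverageTrack, GeneAnnotation

__all__ = [
    "ToyNetworkSpec",
    "ToyGroundTruth",
    "SyntheticSeqSpec",
    "make_toy_network",
    "make_synthetic_coverage",
    "make_mutation_table",
]

_PRECURSOR_FORMULAS = [
    "C3H7NO2",
    "C4H7NO4",
    "C5H9NO4",
    "C4H8N2O3",
    "C6H14N4O2",
    "C5H11NO2S",
    "C9H11NO2",
    "C3H7NO3",
]


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Recipe for a toy network with known auxotrophy structure.

    n_precursors
        Number of biomass precursors (≥1, ≤8).
    biomass_stoich
        Per-precursor biomass coefficients; drawn uniformly from [0.5, 3.0]
        with the spec's seed when omitted.
    isozymes
        Synthesis routes per precursor (1 = a single knockable route).
    alt_substrate_for
        Index of a precursor that additionally has a closed-by-default
        alternative substrate (convertible to the precursor), exercising the
        competing-uptake threshold; None disables it.
    include_decoys
        Add a dead-end large-metabolite reaction and a spontaneous leak so
        candidate filtering and FVA pruning have something to do.
    """

    n_precursors: int = 3
    biomass_stoich: tuple[float, ...] | None = None
    isozymes: tuple[int, ...] | None = None
    alt_substrate_for: int | None = None
    include_decoys: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_precursors <= len(_PRECURSOR_FORMULAS):
            raise ValueError(
                f"n_precursors must be in [1, {len(_PRECURSOR_FORMULAS)}]"
            )
        if self.biomass_stoich is not None and len(self.biomass_stoich) != self.n_precursors:
            raise ValueError("biomass_stoich length must equal n_precursors")
        if self.isozymes is not None and len(self.isozymes) != self.n_precursors:
            raise ValueError("isozymes length must equal n_precursors")
        if self.alt_substrate_for is not None and not (
            0 <= self.alt_substrate_for < self.n_precursors
        ):
            raise ValueError("alt_substrate_for out of range")


@dataclass(frozen=True)
class ToyGroundTruth:
    """Analytically known auxotrophy structure of a generated toy network.

    ``routes[i]`` lists the synthesis-reaction ids of precursor i (the
    conversion from the alternative substrate, when present, is listed
    separately in ``alt_route``). All uptake values follow from mass balance,
    no LP involved.
    """

    biomass_stoich: tuple[float, ...]
    routes: tuple[tuple[str, ...], ...]
    target_exchanges: tuple[str, ...]
    alt_route: str | None
    alt_exchange: str | None
    alt_precursor: int | None
    medium: Medium

    def required_uptake(
        self, precursor: int, growth_rate: float, threshold: float = 0.0,
        alt_route_knocked: bool = False,
    ) -> float:
        """Min uptake of precursor's exchange once all its routes are knocked."""
        base = self.biomass_stoich[precursor] * growth_rate
        if precursor == self.alt_precursor and not alt_route_knocked:
            return max(0.0, base - threshold)
        return base

    def optimal_uptake(
        self, target_precursor: int, n_knockouts: int, growth_rate: float,
        threshold: float = 0.0,
    ) -> float:
        """Best achievable objective for the target with ≤ n_knockouts KOs."""
        cost = len(self.routes[target_precursor])
        best = 0.0
        if n_knockouts >= cost:
            best = self.required_uptake(target_precursor, growth_rate, threshold)
        if (
            target_precursor == self.alt_precursor
            and n_knockouts >= cost + 1
        ):
            best = max(
                best,
                self.required_uptake(
                    target_precursor, growth_rate, threshold, alt_route_knocked=True
                ),
            )
        return best


def make_toy_network(spec: ToyNetworkSpec) -> tuple[MetabolicNetwork, ToyGroundTruth]:
    """Build the toy network and its ground-truth ledger.

    Layout: glucose exchange → transport → cytosolic hub; per precursor one
    or more knockable synthesis routes hub → precursor, a (non-knockable)
    transporter precursor_e ↔ precursor_c, and a closed exchange. Biomass
    consumes every precursor. Transport and exchange reactions carry
    blocklisted subsystems so the knockout-candidate pool is exactly the
    synthesis/conversion routes.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_precursors
    b = (
        tuple(float(x) for x in spec.biomass_stoich)
        if spec.biomass_stoich is not None
        else tuple(float(x) for x in rng.uniform(0.5, 3.0, n).round(3))
    )
    iso = spec.isozymes if spec.isozymes is not None else tuple([1] * n)

    mets = [
        Metabolite("glc_e", "C6H12O6", "e"),
        Metabolite("glc_c", "C6H12O6", "c"),
        Metabolite("nh4_e", "H4N", "e"),
        Metabolite("pi_e", "HO4P", "e"),
    ]
    rxns = [
        Reaction("EX_glc_e", {"glc_e": -1.0}, 0.0, DEFAULT_BOUND, subsystem="Exchange"),
        Reaction("EX_nh4_e", {"nh4_e": -1.0}, 0.0, DEFAULT_BOUND, subsystem="Exchange"),
        Reaction("EX_pi_e", {"pi_e": -1.0}, 0.0, DEFAULT_BOUND, subsystem="Exchange"),
        Reaction(
            "T_glc",
            {"glc_e": -1.0, "glc_c": 1.0},
            0.0,
            DEFAULT_BOUND,
            subsystem="Transport, Inner Membrane",
        ),
    ]

    routes: list[tuple[str, ...]] = []
    target_exchanges: list[str] = []
    biomass_stoich: dict[str, float] = {}
    for i in range(n):
        pc, pe = f"p{i}_c", f"p{i}_e"
        formula = _PRECURSOR_FORMULAS[i]
        mets.append(Metabolite(pc, formula, "c"))
        mets.append(Metabolite(pe, formula, "e"))
        route_ids = []
        for k in range(iso[i]):
            rid = f"SYN_p{i}" if iso[i] == 1 else f"SYN_p{i}_iso{k}"
            route_ids.append(rid)
            rxns.append(
                Reaction(
                    rid,
                    {"glc_c": -1.0, pc: 1.0},
                    0.0,
                    DEFAULT_BOUND,
                    subsystem="Biosynthesis",
                )
            )
        routes.append(tuple(route_ids))
        rxns.append(
            Reaction(
                f"T_p{i}",
                {pe: -1.0, pc: 1.0},
                -DEFAULT_BOUND,
                DEFAULT_BOUND,
                subsystem="Transport, Inner Membrane",
            )
        )
        ex_id = f"EX_p{i}_e"
        target_exchanges.append(ex_id)
        rxns.append(Reaction(ex_id, {pe: -1.0}, 0.0, DEFAULT_BOUND, subsystem="Exchange"))
        biomass_stoich[pc] = -b[i]

    alt_route = alt_exchange = None
    if spec.alt_substrate_for is not None:
        i = spec.alt_substrate_for
        mets.append(Metabolite("alt_e", "C4H6O4", "e"))
        mets.append(Metabolite("alt_c", "C4H6O4", "c"))
        alt_exchange = "EX_alt_e"
        alt_route = "CONV_alt"
        rxns.append(
            Reaction("EX_alt_e", {"alt_e": -1.0}, 0.0, DEFAULT_BOUND, subsystem="Exchange")
        )
        rxns.append(
            Reaction(
                "T_alt",
                {"alt_e": -1.0, "alt_c": 1.0},
                0.0,
                DEFAULT_BOUND,
                subsystem="Transport, Inner Membrane",
            )
        )
        rxns.append(
            Reaction(
                "CONV_alt",
                {"alt_c": -1.0, f"p{i}_c": 1.0},
                0.0,
                DEFAULT_BOUND,
                subsystem="Biosynthesis",
            )
        )

    if spec.include_decoys:
        mets.append(Metabolite("big_c", "C12H22O11", "c"))
        # dead end: FVA prunes it; its 12-carbon metabolite also trips the
        # candidate filter when run unreduced
        rxns.append(
            Reaction("BIG_SYN", {"glc_c": -2.0, "big_c": 1.0}, 0.0, DEFAULT_BOUND)
        )
        rxns.append(
            Reaction(
                "GLC_LEAK",
                {"glc_c": -1.0, "glc_e": 1.0},
                0.0,
                DEFAULT_BOUND,
                is_spontaneous=True,
            )
        )

    rxns.append(Reaction("BIOMASS", dict(biomass_stoich), 0.0, DEFAULT_BOUND))

    order = rng.permutation(len(rxns))
    rxns = [rxns[j] for j in order]
    net = MetabolicNetwork(
        rxns, mets, biomass_reaction_id="BIOMASS", id=f"toy_seed{spec.seed}"
    )
    truth = ToyGroundTruth(
        biomass_stoich=b,
        routes=tuple(routes),
        target_exchanges=tuple(target_exchanges),
        alt_route=alt_route,
        alt_exchange=alt_exchange,
        alt_precursor=spec.alt_substrate_for,
        medium=Medium({"EX_glc_e": 10.0}),
    )
    return net, truth


# ---------------------------------------------------------------------------
# synthetic sequencing data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSeqSpec:
    """Recipe for a synthetic co-culture sequencing sample.

    Planted duplications are (first_gene_index, last_gene_index, multiplicity)
    over whole ORFs (inclusive); overlapping spans are rejected. Knockout-gene
    depletion encodes the true strain fractions: depth over a strain's deleted
    ORF scales with (1 − that strain's fraction). ``negbinom_dispersion`` is
    the gamma shape r (variance = m + m²/r); None selects Poisson noise.
    """

    genome_length: int = 100_000
    n_genes: int = 100
    mean_depth: float = 100.0
    negbinom_dispersion: float | None = None
    planted_duplications: tuple[tuple[int, int, float], ...] = ()
    strain_fractions: tuple[float, float] = (0.5, 0.5)
    strain_names: tuple[str, str] = ("strainA", "strainB")
    ko_genes: tuple[tuple[str, ...], tuple[str, ...]] = (("gene_10",), ("gene_60",))
    markers: tuple[tuple[str, ...], tuple[str, ...]] = (
        ("mkA_1", "mkA_2"),
        ("mkB_1",),
    )
    marker_read_depth: int = 200
    marker_dropout: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.strain_fractions) - 1.0) > 1e-9:
            raise ValueError("strain fractions must sum to 1")
        spans = sorted(self.planted_duplications)
        for (s1, e1, _), (s2, _e2, _m2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("overlapping planted duplications are unsupported")
        for s, e, mult in spans:
            if not (0 <= s <= e < self.n_genes):
                raise ValueError(f"planted span ({s}, {e}) outside the gene set")
            if mult <= 0:
                raise ValueError("multiplicity must be positive")


def _gene_layout(spec: SyntheticSeqSpec) -> list[GeneAnnotation]:
    step = spec.genome_length // spec.n_genes
    glen = max(1, int(step * 0.8))
    return [
        GeneAnnotation(f"gene_{i}", i * step + 1, i * step + glen, "+", order=i)
        for i in range(spec.n_genes)
    ]


def make_synthetic_coverage(
    spec: SyntheticSeqSpec,
) -> tuple[CoverageTrack, list[GeneAnnotation], pd.DataFrame]:
    """Generate the depth track, gene annotations, and a truth table.

    The truth table lists one row per planted event: duplications (with span
    and multiplicity) and knockout depletions (with the owning strain and its
    true fraction).
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_layout(spec)
    by_name = {g.gene_id: g for g in genes}
    expected = np.full(spec.genome_length, float(spec.mean_depth))

    truth_rows = []
    for start_idx, end_idx, mult in spec.planted_duplications:
        lo = genes[start_idx].start - 1
        hi = genes[end_idx].end
        expected[lo:hi] *= mult
        truth_rows.append(
            {
                "event": "duplication",
                "genes": ";".join(g.gene_id for g in genes[start_idx : end_idx + 1]),
                "start": genes[start_idx].start,
                "end": genes[end_idx].end,
                "value": mult,
            }
        )
    for strain, frac, kos in zip(
        spec.strain_names, spec.strain_fractions, spec.ko_genes
    ):
        for name in kos:
            g = by_name[name]
            expected[g.start - 1 : g.end] *= 1.0 - frac
            truth_rows.append(
                {
                    "event": "ko_depletion",
                    "genes": name,
                    "start": g.start,
                    "end": g.end,
                    "value": frac,
                }
            )

    if spec.negbinom_dispersion is None:
        depth = rng.poisson(expected).astype(float)
    else:
        r = spec.negbinom_dispersion
        lam = rng.gamma(shape=r, scale=expected / r)
        depth = rng.poisson(lam).astype(float)

    track = CoverageTrack(depth, sample_id=f"synth_seed{spec.seed}")
    truth = pd.DataFrame(truth_rows, columns=["event", "genes", "start", "end", "value"])
    return track, genes, truth


def make_mutation_table(
    spec: SyntheticSeqSpec,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Generate a marker-frequency table with binomial sampling noise.

    Each marker's observed frequency is Binomial(depth, strain fraction) /
    depth; markers listed in ``marker_dropout`` are omitted, exercising the
    single-marker fallback. Returns the table and the true fractions.
    """
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    truth = dict(zip(spec.strain_names, spec.strain_fractions))
    for strain, frac, marker_ids in zip(
        spec.strain_names, spec.strain_fractions, spec.markers
    ):
        for mid in marker_ids:
            if mid in spec.marker_dropout:
                continue
            freq = rng.binomial(spec.marker_read_depth, frac) / spec.marker_read_depth
            rows.append(
                {
                    "sample": f"synth_seed{spec.seed}",
                    "strain_marker_id": mid,
                    "frequency": freq,
                }
            )
    return pd.DataFrame(rows, columns=["sample", "strain_marker_id", "frequency"]), truth
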