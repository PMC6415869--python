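"""Co-culture sequencing analytics.

Two independent estimators of strain abundance in a two-member co-culture:

* **mutation-based** — each strain carries one or two characteristic
  ("barcode") mutations; the strain's raw abundance is the mean observed
  frequency of its markers (missing markers are dropped, so a strain with one
  detected marker falls back to that single frequency);
* **coverage-based** — reads over a strain's *deleted* gene can only come from
  the partner, so mean depth over the knocked-out ORF divided by genome-wide
  mean depth estimates the **partner's** abundance.

Both estimators are normalized so the two strains' abundances sum to one.

Genome-duplication calling follows a per-gene coverage rule: a gene is
flagged when strictly more than 80% of its ORF bases exceed 1.25× a reference
coverage statistic; flagged genes already duplicated in the starting strains
are removed; surviving genes are grouped along the genome, starting a new
group when more than five genes intervene. Coverage tracks are condensed for
plotting by segment-averaging into 50,000 segments followed by LOWESS with a
0.5% window and no robustness reweightings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess
from scipy import stats

__all__ = [
    "CoverageTrack",
    "GeneAnnotation",
    "CharacteristicMutationSet",
    "AbundanceEstimate",
    "DuplicationCall",
    "DuplicationConfig",
    "SmoothingConfig",
    "AbundanceUndefinedError",
    "abundance_from_mutations",
    "abundance_from_coverage",
    "call_duplications",
    "smooth_coverage",
    "read_coverage_tsv",
    "read_gene_annotations",
    "read_mutation_table",
    "calls_to_frame",
]


class AbundanceUndefinedError(ValueError):
    """No marker of a strain was observed; its abundance cannot be computed."""


@dataclass(frozen=True)
class CoverageTrack:
    """Per-base read depth over 1-based genome positions."""

    depth: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth)
        if depth.ndim != 1:
            raise ValueError("depth must be a 1-D vector")
        if (depth < 0).any():
            raise ValueError("depths must be non-negative")
        object.__setattr__(self, "depth", depth)

    @property
    def genome_length(self) -> int:
        return int(self.depth.size)

    def orf_depth(self, gene: "GeneAnnotation") -> np.ndarray:
        return self.depth[gene.start - 1 : gene.end]


@dataclass(frozen=True)
class GeneAnnotation:
    """1-based inclusive gene coordinates plus genome order index."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    order: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"gene {self.gene_id}: invalid span {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CharacteristicMutationSet:
    """Strain id → list of (marker id, genome position)."""

    markers: dict[str, list[tuple[str, int]]]

    def __post_init__(self) -> None:
        for strain, mks in self.markers.items():
            if not mks:
                raise ValueError(f"strain {strain} has no characteristic mutation")

    @property
    def strains(self) -> list[str]:
        return list(self.markers)


@dataclass(frozen=True)
class AbundanceEstimate:
    sample_id: str
    raw: dict[str, float]
    normalized: dict[str, float]
    method: str  # "mutation" | "coverage"


@dataclass(frozen=True)
class DuplicationConfig:
    threshold_multiplier: float = 1.25
    orf_fraction: float = 0.80
    max_gene_gap: int = 5
    reference_statistic: str = "trimmed_mean"  # fit_mean | trimmed_mean | median

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 1:
            raise ValueError("threshold_multiplier must be > 1")
        if not 0 < self.orf_fraction <= 1:
            raise ValueError("orf_fraction must be in (0, 1]")
        if self.max_gene_gap < 0:
            raise ValueError("max_gene_gap must be >= 0")
        if self.reference_statistic not in ("fit_mean", "trimmed_mean", "median"):
            raise ValueError(f"unknown reference_statistic {self.reference_statistic!r}")


@dataclass(frozen=True)
class SmoothingConfig:
    n_segments: int = 50_000
    lowess_fraction: float = 0.005
    reweightings: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not 0 < self.lowess_fraction <= 1:
            raise ValueError("lowess_fraction must be in (0, 1]")


@dataclass(frozen=True)
class DuplicationCall:
    group_id: int
    member_genes: tuple[str, ...]
    span: tuple[int, int]
    mean_multiplicity: float
    sample_id: str = ""


def _normalize(raw: dict[str, float], sample_id: str, method: str) -> AbundanceEstimate:
    total = sum(raw.values())
    if total <= 0:
        raise AbundanceUndefinedError(
            f"sample {sample_id}: raw abundances sum to {total}; cannot normalize"
        )
    strains = list(raw)
    normalized = {s: raw[s] / total for s in strains[:-1]}
    # complement for the last strain so the pair sums to 1 exactly
    normalized[strains[-1]] = 1.0 - sum(normalized.values())
    return AbundanceEstimate(sample_id, dict(raw), normalized, method)


def abundance_from_mutations(
    frequencies: dict[str, float],
    markers: CharacteristicMutationSet,
    sample_id: str = "",
) -> AbundanceEstimate:
    """Strain abundances from characteristic-mutation frequencies.

    ``frequencies`` maps marker id → observed population frequency in [0, 1];
    markers absent from the mapping are treated as not detected and dropped
    from the strain's average. A strain with no detected marker raises
    :class:`AbundanceUndefinedError` naming it.
    """
    raw: dict[str, float] = {}
    for strain, strain_markers in markers.markers.items():
        observed = [
            frequencies[mid] for mid, _pos in strain_markers if mid in frequencies
        ]
        for f in observed:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"marker frequency {f} outside [0, 1]")
        if not observed:
            raise AbundanceUndefinedError(
                f"sample {sample_id}: no characteristic mutation of strain "
                f"{strain} was detected; abundance undefined"
            )
        raw[strain] = float(np.mean(observed))
    return _normalize(raw, sample_id, "mutation")


def abundance_from_coverage(
    track: CoverageTrack,
    ko_genes: dict[str, list[GeneAnnotation]],
) -> AbundanceEstimate:
    """Strain abundances from read depth over each strain's deleted genes.

    ``ko_genes`` maps strain id → annotations of the gene(s) deleted in that
    strain. Depth over a deleted ORF comes from the *partner*, so with two
    strains the ratio (mean ORF depth / genome mean depth) for strain A's
    deletions is the raw abundance of strain B. Two deleted genes are
    averaged.
    """
    if len(ko_genes) != 2:
        raise ValueError("coverage-based abundance is defined for exactly two strains")
    genome_mean = float(track.depth.mean())
    if genome_mean <= 0:
        raise ValueError("genome-wide mean depth is zero; abundance undefined")
    for strain, genes in ko_genes.items():
        for g in genes:
            if g.end > track.genome_length:
                raise ValueError(f"gene {g.gene_id} extends beyond the genome")
    strains = list(ko_genes)
    raw: dict[str, float] = {}
    for strain, partner in zip(strains, reversed(strains)):
        ratios = [
            float(track.orf_depth(g).mean()) / genome_mean for g in ko_genes[strain]
        ]
        raw[partner] = float(np.mean(ratios))
    return _normalize(raw, track.sample_id, "coverage")


def _reference_depth(track: CoverageTrack, config: DuplicationConfig) -> float:
    if config.reference_statistic == "median":
        return float(np.median(track.depth))
    if config.reference_statistic == "trimmed_mean":
        return float(stats.trim_mean(track.depth, 0.1))
    # fit_mean: mean of the LOWESS-fitted coverage profile
    smoothed = smooth_coverage(track, SmoothingConfig())
    return float(np.mean(smoothed))


def call_duplications(
    track: CoverageTrack,
    genes: list[GeneAnnotation],
    baseline_dups: list[DuplicationCall] = (),
    config: DuplicationConfig = DuplicationConfig(),
) -> list[DuplicationCall]:
    """Flag duplicated genes and group them along the genome.

    A gene is flagged when strictly more than ``orf_fraction`` of its ORF
    bases have depth strictly above ``threshold_multiplier ×`` the reference
    coverage statistic. Genes flagged in the starting strains
    (``baseline_dups``) are removed. Consecutive flagged genes stay in one
    group while at most ``max_gene_gap`` genes intervene; a larger gap starts
    a new group. Mean multiplicity is mean group-ORF depth over the reference.
    """
    genes = sorted(genes, key=lambda g: (g.start, g.end))
    reference = _reference_depth(track, config)
    if reference <= 0:
        return []
    threshold = config.threshold_multiplier * reference

    baseline_genes = set()
    for call in baseline_dups:
        baseline_genes.update(call.member_genes)

    flagged: list[tuple[int, GeneAnnotation]] = []
    for order, gene in enumerate(genes):
        depth = track.orf_depth(gene)
        frac_above = float((depth > threshold).mean())
        if frac_above > config.orf_fraction and gene.gene_id not in baseline_genes:
            flagged.append((order, gene))

    calls: list[DuplicationCall] = []
    group: list[tuple[int, GeneAnnotation]] = []

    def close_group() -> None:
        if not group:
            return
        members = tuple(g.gene_id for _, g in group)
        depths = np.concatenate([track.orf_depth(g) for _, g in group])
        calls.append(
            DuplicationCall(
                group_id=len(calls),
                member_genes=members,
                span=(group[0][1].start, group[-1][1].end),
                mean_multiplicity=float(depths.mean()) / reference,
                sample_id=track.sample_id,
            )
        )

    for order, gene in flagged:
        if group and order - group[-1][0] - 1 > config.max_gene_gap:
            close_group()
            group = []
        group.append((order, gene))
    close_group()
    return calls


def smooth_coverage(
    track: CoverageTrack, config: SmoothingConfig = SmoothingConfig()
) -> np.ndarray:
    """Segment-average the depth vector, then LOWESS-smooth the segment means.

    The genome is split into ``n_segments`` near-equal segments (reduced, with
    a warning, for genomes shorter than the segment count), each segment's
    mean depth is taken, and LOWESS with the configured fraction and zero
    robustness iterations is applied over segment index. Output length equals
    the (possibly reduced) segment count.
    """
    n = config.n_segments
    L = track.genome_length
    if L < n:
        warnings.warn(
            f"genome of {L} bp is shorter than {n} segments; using {L} segments",
            stacklevel=2,
        )
        n = L
    edges = np.linspace(0, L, n + 1).round().astype(int)
    sums = np.add.reduceat(track.depth.astype(float), edges[:-1])
    widths = np.diff(edges)
    means = sums / np.maximum(widths, 1)
    x = np.arange(n, dtype=float)
    smoothed = lowess(
        means,
        x,
        frac=config.lowess_fraction,
        it=config.reweightings,
        return_sorted=False,
    )
    return np.asarray(smoothed)


# ---------------------------------------------------------------------------
# text-format I/O
# ---------------------------------------------------------------------------


def read_coverage_tsv(path, sample_id: str | None = None) -> CoverageTrack:
    """Read a 2-column (position, depth) TSV into a dense per-base track.

    Positions are 1-based; positions missing from the file get depth 0.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["pos", "depth"], comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty coverage file")
    length = int(df["pos"].max())
    depth = np.zeros(length)
    depth[df["pos"].to_numpy() - 1] = df["depth"].to_numpy()
    return CoverageTrack(depth, sample_id or Path(path).stem)


def read_gene_annotations(path) -> list[GeneAnnotation]:
    """Read gene annotations from BED (0-based half-open) or GFF3 (1-based).

    Coordinates are converted to the package's 1-based inclusive convention at
    this boundary. Genes are returned in genome order.
    """
    import pyranges as pr

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        df = pr.read_bed(str(path), as_df=True)
        names = df["Name"] if "Name" in df else df.index.astype(str)
        genes = [
            GeneAnnotation(
                gene_id=str(name),
                start=int(start) + 1,  # BED is 0-based half-open
                end=int(end),
                strand=str(strand) if strand in ("+", "-") else "+",
            )
            for name, start, end, strand in zip(
                names, df["Start"], df["End"], df.get("Strand", ["+"] * len(df))
            )
        ]
    elif suffix in (".gff", ".gff3", ".gtf"):
        df = pr.read_gff3(str(path), as_df=True)
        df = df[df["Feature"].isin(["gene", "CDS"])] if "Feature" in df else df
        id_col = next(
            (c for c in ("ID", "gene_id", "Name") if c in df.columns), None
        )
        names = df[id_col] if id_col else df.index.astype(str)
        genes = [
            GeneAnnotation(
                gene_id=str(name),
                start=int(start) + 1,  # pyranges stores 0-based starts
                end=int(end),
                strand=str(strand) if strand in ("+", "-") else "+",
            )
            for name, start, end, strand in zip(
                names, df["Start"], df["End"], df["Strand"]
            )
        ]
    else:
        raise ValueError(f"unknown annotation format: {path}")
    genes.sort(key=lambda g: (g.start, g.end))
    return [
        GeneAnnotation(g.gene_id, g.start, g.end, g.strand, order=i)
        for i, g in enumerate(genes)
    ]


def read_mutation_table(path) -> pd.DataFrame:
    """Read a marker-frequency CSV with columns (sample, strain_marker_id, frequency)."""
    df = pd.read_csv(path)
    required = {"sample", "strain_marker_id", "frequency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def calls_to_frame(calls: list[DuplicationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "group_id": c.group_id,
                "start": c.span[0],
                "end": c.span[1],
                "n_genes": len(c.member_genes),
                "genes": ";".join(c.member_genes),
                "mean_multiplicity": c.mean_multiplicity,
            }
            for c in calls
        ],
        columns=[
            "sample",
            "group_id",
            "start",
            "end",
            "n_genes",
            "genes",
            "mean_multiplicity",
        ],
    )
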