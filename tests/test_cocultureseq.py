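"""Strain-abundance estimation, duplication calling, coverage smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from auxodesign import (
    AbundanceUndefinedError,
    CharacteristicMutationSet,
    CoverageTrack,
    DuplicationConfig,
    GeneAnnotation,
    SmoothingConfig,
    abundance_from_coverage,
    abundance_from_mutations,
    call_duplications,
    smooth_coverage,
)
from auxodesign.cocultureseq import (
    DuplicationCall,
    read_coverage_tsv,
    read_gene_annotations,
)

MARKERS = CharacteristicMutationSet(
    {"strainA": [("mkA_1", 100), ("mkA_2", 200)], "strainB": [("mkB_1", 300)]}
)


class TestMutationAbundance:
    def test_averaging_and_normalization(self):
        est = abundance_from_mutations(
            {"mkA_1": 0.5, "mkA_2": 0.6, "mkB_1": 0.4}, MARKERS
        )
        assert est.raw == {"strainA": pytest.approx(0.55), "strainB": pytest.approx(0.4)}
        assert est.normalized["strainA"] == pytest.approx(0.55 / 0.95)
        assert est.normalized["strainB"] == pytest.approx(0.40 / 0.95)

    def test_missing_marker_fallback(self):
        """With one of two markers undetected, the observed one stands alone."""
        est = abundance_from_mutations({"mkA_2": 0.6, "mkB_1": 0.4}, MARKERS)
        assert est.raw["strainA"] == pytest.approx(0.6)

    def test_symmetric_half(self):
        est = abundance_from_mutations({"mkA_1": 0.5, "mkA_2": 0.5, "mkB_1": 0.5}, MARKERS)
        assert est.normalized == {"strainA": 0.5, "strainB": 0.5}

    def test_no_marker_for_strain_errors(self):
        with pytest.raises(AbundanceUndefinedError, match="strainB"):
            abundance_from_mutations({"mkA_1": 0.5}, MARKERS)

    def test_frequency_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            abundance_from_mutations({"mkA_1": 1.5, "mkB_1": 0.4}, MARKERS)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        fa=st.floats(0.01, 0.99),
        fb=st.floats(0.01, 0.99),
    )
    def test_normalized_pair_sums_to_one(self, fa, fb):
        est = abundance_from_mutations({"mkA_1": fa, "mkA_2": fa, "mkB_1": fb}, MARKERS)
        assert sum(est.normalized.values()) == 1.0


class TestCoverageAbundance:
    def _genes(self):
        return {
            "strainA": [GeneAnnotation("hisD", 1001, 2000)],
            "strainB": [GeneAnnotation("pyrC", 5001, 6000)],
        }

    def test_depleted_orf_estimates_partner(self):
        # 70/30 A/B mix: strain A's deleted ORF shows only strain B's reads,
        # i.e. ~30% of the genome-wide mean depth
        depth = np.full(100_000, 100.0)
        depth[1000:2000] = 30.0
        track = CoverageTrack(depth)
        est = abundance_from_coverage(track, self._genes())
        # raw estimate attributed to the partner of the deletion's owner
        assert est.raw["strainB"] == pytest.approx(0.3, abs=0.02)

    def test_two_ko_genes_averaged(self):
        depth = np.full(100_000, 100.0)
        depth[1000:2000] = 20.0
        depth[3000:4000] = 40.0
        genes = {
            "strainA": [
                GeneAnnotation("g1", 1001, 2000),
                GeneAnnotation("g2", 3001, 4000),
            ],
            "strainB": [GeneAnnotation("g3", 5001, 6000)],
        }
        est = abundance_from_coverage(CoverageTrack(depth), genes)
        assert est.raw["strainB"] == pytest.approx(0.30, abs=0.02)

    def test_zero_mean_depth_errors(self):
        with pytest.raises(ValueError, match="zero"):
            abundance_from_coverage(CoverageTrack(np.zeros(100)), self._genes())

    def test_gene_outside_genome_errors(self):
        genes = {
            "strainA": [GeneAnnotation("g", 90, 200)],
            "strainB": [GeneAnnotation("h", 1, 50)],
        }
        with pytest.raises(ValueError, match="beyond"):
            abundance_from_coverage(CoverageTrack(np.full(100, 10.0)), genes)


def _tiled_genes(n, glen=80, step=100):
    return [
        GeneAnnotation(f"g{i}", i * step + 1, i * step + glen, order=i)
        for i in range(n)
    ]


class TestCallDuplications:
    def _flat_track(self, n_genes=30, depth=100.0):
        return CoverageTrack(np.full(n_genes * 100, depth))

    def test_flat_coverage_no_calls(self):
        track = self._flat_track()
        assert call_duplications(track, _tiled_genes(30)) == []

    def test_planted_duplication_called_with_multiplicity(self):
        genes = _tiled_genes(30)
        depth = np.full(3000, 100.0)
        depth[genes[10].start - 1 : genes[12].end] = 200.0
        calls = call_duplications(CoverageTrack(depth), genes)
        assert len(calls) == 1
        assert calls[0].member_genes == ("g10", "g11", "g12")
        assert calls[0].mean_multiplicity == pytest.approx(2.0, rel=0.05)

    def test_partial_orf_below_fraction_not_called(self):
        """Duplication over 70% of the ORF misses the >80% rule."""
        genes = _tiled_genes(30)
        depth = np.full(3000, 100.0)
        g = genes[5]
        n_dup = int(g.length * 0.7)
        depth[g.start - 1 : g.start - 1 + n_dup] = 200.0
        assert call_duplications(CoverageTrack(depth), genes) == []

    @pytest.mark.parametrize("gap,n_groups", [(5, 1), (6, 2)])
    def test_gap_grouping_boundary(self, gap, n_groups):
        """Exactly five intervening genes keep one group; six split it."""
        genes = _tiled_genes(30)
        depth = np.full(3000, 100.0)
        first, second = 5, 5 + gap + 1
        for idx in (first, second):
            g = genes[idx]
            depth[g.start - 1 : g.end] = 200.0
        calls = call_duplications(CoverageTrack(depth), genes)
        assert len(calls) == n_groups

    def test_baseline_duplications_excluded(self):
        genes = _tiled_genes(30)
        depth = np.full(3000, 100.0)
        depth[genes[7].start - 1 : genes[7].end] = 200.0
        baseline = [DuplicationCall(0, ("g7",), (genes[7].start, genes[7].end), 2.0)]
        assert call_duplications(CoverageTrack(depth), genes, baseline) == []

    def test_monotone_in_multiplier(self, seq_sample):
        """Raising the threshold multiplier never adds calls."""
        _, track, genes, _ = seq_sample
        called_genes = None
        for mult in (1.1, 1.25, 1.5, 1.9):
            config = DuplicationConfig(threshold_multiplier=mult)
            calls = call_duplications(track, genes, config=config)
            now = {g for c in calls for g in c.member_genes}
            if called_genes is not None:
                assert now <= called_genes
            called_genes = now

    def test_reference_statistic_variants(self, seq_sample):
        _, track, genes, truth = seq_sample
        planted = set(truth.loc[truth.event == "duplication", "genes"].iloc[0].split(";"))
        for stat in ("trimmed_mean", "median", "fit_mean"):
            calls = call_duplications(
                track, genes, config=DuplicationConfig(reference_statistic=stat)
            )
            found = {g for c in calls for g in c.member_genes}
            assert planted <= found


def _reference_lowess(y, frac):
    """Independent tricube-weighted local linear regression (small n only)."""
    n = len(y)
    x = np.arange(n, dtype=float)
    k = int(np.ceil(frac * n))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        dmax = np.sort(d)[k - 1]
        w = np.clip(1 - (d / max(dmax, 1e-12)) ** 3, 0, None) ** 3
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        slope = (w * (x - xm) * (y - ym)).sum() / sxx if sxx > 1e-12 else 0.0
        out[i] = ym + slope * (x[i] - xm)
    return out


class TestSmoothCoverage:
    def test_constant_coverage_preserved(self):
        track = CoverageTrack(np.full(5000, 42.0))
        smoothed = smooth_coverage(track, SmoothingConfig(n_segments=50, lowess_fraction=0.1))
        assert np.allclose(smoothed, 42.0)

    def test_segment_count_and_length(self):
        """A 5 Mbp genome split into 50,000 segments gives ~100 bp segments."""
        track = CoverageTrack(np.ones(5_000_000))
        smoothed = smooth_coverage(track, SmoothingConfig())
        assert len(smoothed) == 50_000

    def test_short_genome_falls_back_with_warning(self):
        track = CoverageTrack(np.full(1000, 5.0))
        with pytest.warns(UserWarning, match="shorter"):
            smoothed = smooth_coverage(track, SmoothingConfig(n_segments=5000))
        assert len(smoothed) == 1000

    def test_step_function_matches_reference_lowess(self):
        """Smoothing a step agrees with an independent tricube local fit."""
        rng = np.random.default_rng(5)
        base = np.full(20_000, 100.0)
        base[10_000:] = 200.0
        track = CoverageTrack(rng.poisson(base).astype(float))
        config = SmoothingConfig(n_segments=200, lowess_fraction=0.2)
        ours = smooth_coverage(track, config)
        # rebuild the segment means exactly as the implementation defines them
        seg_means = track.depth.reshape(200, -1).mean(axis=1)
        expected = _reference_lowess(seg_means, 0.2)
        assert np.allclose(ours, expected, atol=1e-6)


class TestTextIO:
    def test_coverage_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "cov.tsv"
        path.write_text("".join(f"{i}\t{i * 2}\n" for i in range(1, 101)))
        track = read_coverage_tsv(path)
        assert track.genome_length == 100
        assert track.depth[0] == 2 and track.depth[99] == 200

    def test_bed_annotations_converted_to_one_based(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("chr\t0\t100\tgeneA\t0\t+\nchr\t150\t300\tgeneB\t0\t-\n")
        genes = read_gene_annotations(path)
        assert [g.gene_id for g in genes] == ["geneA", "geneB"]
        assert (genes[0].start, genes[0].end) == (1, 100)
        assert (genes[1].start, genes[1].end) == (151, 300)
        assert genes[1].strand == "-"
        assert [g.order for g in genes] == [0, 1]

    def test_gff3_annotations(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr\tsrc\tgene\t1\t100\t.\t+\t.\tID=geneA\n"
            "chr\tsrc\tgene\t151\t300\t.\t-\t.\tID=geneB\n"
        )
        genes = read_gene_annotations(path)
        assert [g.gene_id for g in genes] == ["geneA", "geneB"]
        assert (genes[0].start, genes[0].end) == (1, 100)
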