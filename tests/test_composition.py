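import numpy as np
import pytest

from teprofiler.composition import (
    contribution_of_features,
    cpg_state_counts,
    expression_ratio,
    kruskal_across_categories,
    proportion_in_states,
    signal_metaprofile,
    state_bp_in_features,
)
from teprofiler.core import (
    CoverageTrack,
    GenomeAssembly,
    GenomicInterval,
    MethylationTrack,
)
from teprofiler.intervals import merge, overlap_bp, total_bp

from conftest import expand_states, make_segmentation, make_te


class TestIntervalArithmetic:
    def test_merge_collapses_overlaps(self):
        arrays = merge([GenomicInterval("chr1", 0, 100),
                        GenomicInterval("chr1", 50, 150),
                        GenomicInterval("chr1", 200, 300)])
        starts, ends = arrays["chr1"]
        assert starts.tolist() == [0, 200]
        assert ends.tolist() == [150, 300]
        assert total_bp(arrays) == 250

    def test_overlap_bp_sweep(self):
        a = merge([GenomicInterval("chr1", 0, 100)])
        b = merge([GenomicInterval("chr1", 50, 70),
                   GenomicInterval("chr1", 90, 200)])
        assert overlap_bp(a, b) == 30


class TestProportions:
    def test_single_state_te(self):
        seg = make_segmentation([(0, 400, "7_Enh")])
        counts = state_bp_in_features([make_te(0, 100)], seg)
        assert counts["7_Enh"] == 100
        assert counts.drop("7_Enh").sum() == 0

    def test_split_te_base_counting(self):
        seg = make_segmentation([(0, 600, "7_Enh"), (600, 1000, "15_Quies")])
        te = make_te(540, 640)
        counts = state_bp_in_features([te], seg)
        assert counts["7_Enh"] == 60 and counts["15_Quies"] == 40
        table = proportion_in_states([te], segmentations={"E1": seg})
        assert table.loc["E1", "7_Enh"] == pytest.approx(0.6)
        assert table.loc["E1", "15_Quies"] == pytest.approx(0.4)

    def test_proportions_sum_to_one(self, dataset):
        table = proportion_in_states(dataset.tes[:500],
                                     segmentations=dataset.segmentations)
        assert np.allclose(table.sum(axis=1), 1.0, atol=1e-9)

    def test_brute_force_agreement_on_toy_chromosome(self, dataset):
        """Base counting by interval sweep equals a per-base scan."""
        epi = dataset.epigenome_ids[0]
        seg = dataset.segmentations[epi]
        tes = [t for t in dataset.tes if t.interval.chrom == "chr1"][:400]
        counts = state_bp_in_features(tes, seg)
        base = expand_states(seg, "chr1")
        inside = np.zeros(len(base), dtype=bool)
        for t in tes:
            inside[t.interval.start:t.interval.end] = True
        brute = np.bincount(base[inside], minlength=len(seg.state_alphabet))
        assert counts.to_numpy().tolist() == brute.tolist()


class TestHalfCpGRule:
    def test_cpg_straddling_boundary_counts_half(self):
        # CpG with C at 99: G at 100 is outside the feature [0, 100)
        track = MethylationTrack("E1", {"chr1": (
            np.array([20, 99]), np.array([0.1, 0.1]), np.array([10, 10]))})
        counts = cpg_state_counts([GenomicInterval("chr1", 0, 100)], track)
        assert counts["hypo"] == pytest.approx(1.5)

    def test_low_coverage_accrues_to_missing(self):
        track = MethylationTrack("E1", {"chr1": (
            np.array([20, 40]), np.array([0.1, 0.9]), np.array([3, 10]))})
        counts = cpg_state_counts([GenomicInterval("chr1", 0, 100)], track)
        assert counts["missing"] == 1.0 and counts["hyper"] == 1.0


class TestContribution:
    def test_full_containment_gives_one(self):
        seg = make_segmentation([(0, 200, "7_Enh"), (200, 1000, "15_Quies")])
        table = contribution_of_features(
            [make_te(0, 400)], {"E1": seg})
        row = table[(table.epigenome == "E1") & (table.state == "7_Enh")
                    & (table.feature_set == "all_features")]
        assert row.fraction.iloc[0] == pytest.approx(1.0)

    def test_counting_fraction(self):
        seg = make_segmentation([(0, 1200, "7_Enh"), (1200, 2000, "15_Quies")])
        table = contribution_of_features([make_te(100, 400)], {"E1": seg})
        row = table[(table.epigenome == "E1") & (table.state == "7_Enh")
                    & (table.feature_set == "all_features")]
        assert row.fraction.iloc[0] == pytest.approx(300 / 1200)

    def test_class_decomposition_sums_to_total(self, dataset):
        by_class = {}
        for te in dataset.tes:
            by_class.setdefault(te.te_class, []).append(te)
        table = contribution_of_features(dataset.tes, dataset.segmentations,
                                         class_features=by_class)
        pooled = table[table.epigenome == "all"]
        for state in dataset.segmentations[dataset.epigenome_ids[0]].state_alphabet:
            sub = pooled[pooled.state == state]
            total = sub[sub.feature_set == "all_features"].fraction.iloc[0]
            parts = sub[sub.feature_set != "all_features"].fraction.sum()
            assert parts == pytest.approx(total, abs=1e-9)

    def test_partition_contributions_sum_to_one(self):
        """Features partitioning the genome contribute 1 per state."""
        seg = make_segmentation([(0, 600, "7_Enh"), (600, 1000, "15_Quies")])
        left = [GenomicInterval("chr1", 0, 500)]
        right = [GenomicInterval("chr1", 500, 1000)]
        t1 = contribution_of_features(left, {"E1": seg})
        t2 = contribution_of_features(right, {"E1": seg})
        for state in ("7_Enh", "15_Quies"):
            f1 = t1[(t1.epigenome == "E1") & (t1.state == state)
                    & (t1.feature_set == "all_features")].fraction.iloc[0]
            f2 = t2[(t2.epigenome == "E1") & (t2.state == state)
                    & (t2.feature_set == "all_features")].fraction.iloc[0]
            assert f1 + f2 == pytest.approx(1.0)

    def test_pooled_equals_count_weighted_mean(self, dataset):
        """Pooling sums numerators and denominators, which equals the
        observation-weighted mean of per-epigenome fractions."""
        tes = dataset.tes[:800]
        table = contribution_of_features(tes, dataset.segmentations)
        state = "15_Quies"
        per_epi = table[(table.state == state) & (table.epigenome != "all")
                        & (table.feature_set == "all_features")]
        pooled = table[(table.state == state) & (table.epigenome == "all")
                       & (table.feature_set == "all_features")].fraction.iloc[0]
        dens = []
        for epi in per_epi.epigenome:
            seg = dataset.segmentations[epi]
            dens.append(seg.state_bp()[list(seg.state_alphabet).index(state)])
        dens = np.array(dens, dtype=float)
        weighted = float((per_epi.fraction.to_numpy() * dens).sum() / dens.sum())
        assert pooled == pytest.approx(weighted, rel=1e-9)


class TestExpressionRatio:
    def _assembly(self):
        return GenomeAssembly("t", [("chr1", 1000)])

    def test_uniform_expression_ratio_one(self):
        track = CoverageTrack("E1", {"chr1": (np.array([0, 1000]),
                                              np.array([3.0]))})
        r = expression_ratio([make_te(100, 200)], {"E1": track},
                             self._assembly())
        assert r["E1"] == pytest.approx(1.0)

    def test_half_expression_ratio(self):
        track = CoverageTrack("E1", {"chr1": (
            np.array([0, 500, 1000]), np.array([1.0, 3.0]))})
        # TE covers signal 1.0; genome mean is 2.0
        r = expression_ratio([make_te(0, 500)], {"E1": track},
                             self._assembly())
        assert r["E1"] == pytest.approx(0.5)

    def test_zero_genome_signal_is_nan(self):
        track = CoverageTrack("E1", {"chr1": (np.array([0, 1000]),
                                              np.array([0.0]))})
        r = expression_ratio([make_te(0, 500)], {"E1": track},
                             self._assembly())
        assert np.isnan(r["E1"])


class TestMetaprofile:
    def test_constant_signal_fills_all_bins(self):
        asm = GenomeAssembly("t", [("chr1", 40_000)])
        track = CoverageTrack("E1", {"chr1": (np.array([0, 40_000]),
                                              np.array([2.5]))})
        prof = signal_metaprofile([make_te(19_000, 20_000)], track, asm)
        assert prof.shape == (200,)
        assert np.allclose(prof, 2.5)

    def test_boxcar_geometry(self):
        asm = GenomeAssembly("t", [("chr1", 40_000)])
        # signal 1.0 exactly over the 1 kb TE body, 0 elsewhere
        track = CoverageTrack("E1", {"chr1": (
            np.array([19_500, 20_500]), np.array([1.0]))})
        prof = signal_metaprofile([make_te(19_500, 20_500)], track, asm)
        assert np.allclose(prof[90:110], 1.0)
        assert np.allclose(prof[:90], 0.0) and np.allclose(prof[110:], 0.0)

    def test_overflow_te_excluded(self):
        asm = GenomeAssembly("t", [("chr1", 12_000)])
        track = CoverageTrack("E1", {"chr1": (np.array([0, 12_000]),
                                              np.array([1.0]))})
        with pytest.raises(ValueError):
            signal_metaprofile([make_te(100, 200)], track, asm)


def test_kruskal_separates_shifted_groups(dataset):
    meta = dataset.metadata
    values = {e: (10.0 if meta[e].group in ("Blood", "ESC") else 0.0)
              + 0.01 * i for i, e in enumerate(sorted(meta))}
    stat, p = kruskal_across_categories(values, meta, "group")
    assert p < 0.05
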