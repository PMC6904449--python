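import numpy as np
import pytest

from teprofiler.annotate import (
    annotate_chromhmm,
    annotate_expression,
    annotate_methylation,
    annotate_peaks,
    build_state_call_matrix,
    primary_chromhmm_state,
)
from teprofiler.core import (
    CoverageTrack,
    GenomicInterval,
    MethylationTrack,
    PeakSet,
    Segmentation,
)
from teprofiler.nulls import association_stats

from conftest import (
    brute_force_chromhmm,
    brute_force_summits,
    make_segmentation,
    make_te,
)


class TestChromhmmAnnotation:
    def test_window_centers_inside_te(self):
        seg = make_segmentation([(0, 400, "7_Enh")])
        # centers 100 and 300 both inside [100, 400)
        assert annotate_chromhmm(make_te(100, 400), seg) == {"7_Enh"}

    def test_largest_overlap_fallback_for_centerless_te(self):
        seg = make_segmentation([(0, 200, "15_Quies"), (200, 400, "7_Enh")])
        # TE [150, 260): centers 100, 300 not contained; overlaps 50 bp
        # of 15_Quies vs 60 bp of 7_Enh
        assert annotate_chromhmm(make_te(150, 260), seg) == {"7_Enh"}

    def test_strict_mode_drops_fallback(self):
        seg = make_segmentation([(0, 200, "15_Quies"), (200, 400, "7_Enh")])
        assert annotate_chromhmm(make_te(150, 260), seg,
                                 mode="window_center_strict") == frozenset()

    def test_block_center_mode(self):
        seg = make_segmentation([(0, 600, "7_Enh"), (600, 800, "15_Quies")])
        # block centers: 300 (7_Enh) and 700 (15_Quies)
        assert annotate_chromhmm(make_te(250, 350), seg,
                                 mode="block_center") == {"7_Enh"}
        assert annotate_chromhmm(make_te(350, 450), seg,
                                 mode="block_center") == frozenset()

    def test_free_form_uses_any_overlap(self):
        seg = Segmentation("E1", ("A", "B"), {
            "chr1": (np.array([0, 150, 500]), np.array(["A", "B"]))
        }, window_bp=None)
        assert annotate_chromhmm(make_te(140, 160), seg) == {"A", "B"}

    def test_uncovered_chromosome_is_no_call_not_empty(self):
        seg = make_segmentation([(0, 400, "7_Enh")])
        assert annotate_chromhmm(make_te(0, 100, chrom="chr2"), seg) is None

    def test_fallback_tie_broken_by_alphabet_order(self):
        seg = make_segmentation([(0, 200, "9_Het"), (200, 400, "7_Enh")],
                                alphabet=("15_Quies", "7_Enh", "1_TssA", "9_Het"))
        # TE [150, 250): 50 bp of each; 7_Enh precedes 9_Het in alphabet
        assert annotate_chromhmm(make_te(150, 250), seg) == {"7_Enh"}

    def test_primary_state_is_largest_overlap(self):
        seg = make_segmentation([(0, 200, "15_Quies"), (200, 400, "7_Enh")])
        assert primary_chromhmm_state(make_te(100, 400), seg) == "7_Enh"


class TestMethylationAnnotation:
    def _track(self, rows):
        pos = np.array([r[0] for r in rows])
        frac = np.array([r[1] for r in rows], dtype=float)
        cov = np.array([r[2] for r in rows])
        return MethylationTrack("E1", {"chr1": (pos, frac, cov)})

    def test_mean_over_well_covered_cpgs(self):
        track = self._track([(120, 0.1, 10), (180, 0.2, 10)])
        mean, state = annotate_methylation(make_te(100, 400), track)
        assert mean == pytest.approx(0.15)
        assert state == "hypo"

    @pytest.mark.parametrize("frac,state", [
        (0.29, "hypo"), (0.30, "intermediate"), (0.70, "intermediate"),
        (0.71, "hyper"),
    ])
    def test_boundary_bins_inclusive_intermediate(self, frac, state):
        track = self._track([(120, frac, 10)])
        assert annotate_methylation(make_te(100, 400), track)[1] == state

    def test_all_low_coverage_is_missing(self):
        track = self._track([(120, 0.5, 3), (180, 0.5, 2)])
        mean, state = annotate_methylation(make_te(100, 400), track)
        assert mean is None and state == "missing"

    def test_no_cpgs_distinct_from_missing(self):
        track = self._track([(500, 0.5, 10)])
        assert annotate_methylation(make_te(100, 400), track)[1] == "no_cpg"

    def test_cpg_straddling_te_start_counts(self):
        # CpG at 99 occupies [99, 101): overlaps TE [100, 400) by one base
        track = self._track([(99, 0.9, 10)])
        mean, state = annotate_methylation(make_te(100, 400), track)
        assert state == "hyper"


class TestPeakAnnotation:
    def _peaks(self, summits):
        peaks = [(GenomicInterval("chr1", max(0, s - 50), s + 50), min(s, 50))
                 for s in summits]
        return PeakSet("E1", "DHS", peaks)

    def test_half_open_summit_containment(self):
        ps = self._peaks([150, 399, 400])
        assert annotate_peaks(make_te(100, 400), ps) == 2

    def test_distinct_positions_counted_once(self):
        ps = self._peaks([150, 150, 200])
        assert annotate_peaks(make_te(100, 400), ps) == 2

    def test_many_peaks_all_counted(self):
        ps = self._peaks(list(range(110, 280, 10)))
        assert annotate_peaks(make_te(100, 400), ps) == 17


class TestExpressionAnnotation:
    def test_constant_signal_scaled_by_factor(self):
        track = CoverageTrack("E1", {
            "chr1": (np.array([0, 1000]), np.array([2.0]))
        }, normalization_factor=0.5)
        assert annotate_expression(make_te(100, 400), track) == pytest.approx(1.0)

    def test_length_weighted_mean(self):
        track = CoverageTrack("E1", {
            "chr1": (np.array([100, 250, 400]), np.array([4.0, 0.0]))
        })
        assert annotate_expression(make_te(100, 400), track) == pytest.approx(2.0)

    def test_absent_chromosome_returns_none(self):
        track = CoverageTrack("E1", {
            "chr1": (np.array([0, 1000]), np.array([2.0]))
        })
        assert annotate_expression(make_te(0, 100, chrom="chrY"), track) is None


class TestStateCallMatrix:
    def test_every_cell_has_a_state_in_default_mode(self, dataset, matrix):
        called = matrix.membership.any(axis=2) | matrix.nocall
        assert called.all()
        assert not matrix.nocall.any()  # toy segmentations cover all chroms

    def test_epigenome_without_wgbs_is_absent_not_zero(self, dataset):
        m = build_state_call_matrix(
            dataset.tes[:50], dataset.segmentations,
            methylation={k: v for k, v in list(dataset.methylation.items())[:1]},
        )
        epi_with = sorted(dataset.methylation)[0]
        k_with = m.epi_index[epi_with]
        absent_cols = [k for k in range(m.n_epigenomes) if k != k_with]
        assert (m.meth_state[:, absent_cols] == -1).all()
        assert (m.meth_state[:, k_with] != -1).any()

    def test_chromosome_missing_from_one_epigenome_is_no_call(self, dataset):
        epi = dataset.epigenome_ids[0]
        seg = dataset.segmentations[epi]
        partial = Segmentation(
            epi, seg.state_alphabet,
            {"chr1": seg.blocks["chr1"]}, window_bp=seg.window_bp)
        segs = dict(dataset.segmentations)
        segs[epi] = partial
        m = build_state_call_matrix(dataset.tes, segs)
        chr2 = np.array([te.interval.chrom == "chr2" for te in dataset.tes])
        k = m.epi_index[epi]
        assert m.nocall[chr2, k].all()
        assert not m.nocall[~chr2, k].any()

    def test_duplicate_te_ids_rejected(self, dataset):
        tes = [dataset.tes[0], dataset.tes[0]]
        with pytest.raises(Exception, match="dupl"):
            build_state_call_matrix(tes, dataset.segmentations)


class TestOracleEquivalence:
    def test_chromhmm_and_peaks_match_per_base_scan(self, dataset):
        """The interval engine reproduces a per-base brute force exactly
        on a random sample of toy TEs, in every annotation mode."""
        rng = np.random.default_rng(0)
        idx = rng.choice(len(dataset.tes), size=300, replace=False)
        epi = dataset.epigenome_ids[0]
        seg = dataset.segmentations[epi]
        peaks = dataset.dhs_peaks[epi]
        summits = peaks.summit_positions()
        for i in idx:
            te = dataset.tes[i]
            for mode in ("window_center", "window_center_strict",
                         "block_center", "any_overlap"):
                got = annotate_chromhmm(te, seg, mode=mode)
                want = brute_force_chromhmm(te, seg, mode=mode)
                want = frozenset(seg.state_alphabet[c] for c in want)
                assert got == want, (te.id, mode)
            assert annotate_peaks(te, peaks, summits) == \
                brute_force_summits(te, peaks)


class TestModeOrdering:
    def test_strict_subset_default_subset_any_overlap(self, dataset):
        """Per TE per epigenome, the strict state set is contained in the
        default set, which is contained in the any-overlap set."""
        strict = build_state_call_matrix(dataset.tes, dataset.segmentations,
                                         mode="window_center_strict")
        default = build_state_call_matrix(dataset.tes, dataset.segmentations,
                                          mode="window_center")
        anyov = build_state_call_matrix(dataset.tes, dataset.segmentations,
                                        mode="any_overlap")
        assert not (strict.membership & ~default.membership).any()
        assert not (default.membership & ~anyov.membership).any()


def test_active_states_concord_with_peaks_and_hypomethylation(matrix):
    """On synthetic data, TEs in active chromHMM states overlap peak
    summits and are hypomethylated more often than other TEs."""
    active = matrix.state_mask(list(
        ("1_TssA", "2_TssAFlnk", "3_TxFlnk", "6_EnhG", "7_Enh")))
    has_dhs = matrix.dhs >= 0
    hit = matrix.dhs > 0
    table = np.array([
        [int((active & hit & has_dhs).sum()),
         int((active & ~hit & has_dhs).sum())],
        [int((~active & hit & has_dhs).sum()),
         int((~active & ~hit & has_dhs).sum())],
    ])
    chi2, p, _ = association_stats(table)
    odds = (table[0, 0] * table[1, 1]) / max(table[0, 1] * table[1, 0], 1)
    assert p < 0.01 and odds > 1

    hypo = matrix.meth_state == 0
    has_meth = matrix.meth_state >= 0
    table = np.array([
        [int((active & hypo & has_meth).sum()),
         int((active & ~hypo & has_meth).sum())],
        [int((~active & hypo & has_meth).sum()),
         int((~active & ~hypo & has_meth).sum())],
    ])
    chi2, p, _ = association_stats(table)
    odds = (table[0, 0] * table[1, 1]) / max(table[0, 1] * table[1, 0], 1)
    assert p < 0.01 and odds > 1
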