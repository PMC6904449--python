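import numpy as np
import pytest
from scipy import stats

from teprofiler.core import GenomeAssembly, GenomicInterval
from teprofiler.intervals import merge, overlap_bp
from teprofiler.nulls import (
    ShuffleSpec,
    association_stats,
    permutation_category_test,
    preferential_enrichment_test,
    shuffle_tes,
)
from teprofiler.simulate import default_metadata

from conftest import make_te


class TestShuffle:
    def test_lengths_and_labels_conserved(self, dataset):
        shuffled = shuffle_tes(dataset.tes, dataset.assembly,
                               ShuffleSpec(n_iterations=2, seed=3))
        for it in shuffled:
            assert len(it) == len(dataset.tes)
            assert sorted(t.interval.width for t in it) == \
                sorted(t.interval.width for t in dataset.tes)
            assert {t.subfamily for t in it} == \
                {t.subfamily for t in dataset.tes}

    def test_no_shuffled_base_in_gaps(self, dataset):
        shuffled = shuffle_tes(dataset.tes, dataset.assembly,
                               ShuffleSpec(n_iterations=1, seed=4))[0]
        gaps = merge(dataset.assembly.gaps)
        placed = merge(t.interval for t in shuffled)
        assert overlap_bp(gaps, placed) == 0

    def test_reproducible_per_iteration(self, dataset):
        a = shuffle_tes(dataset.tes[:100], dataset.assembly,
                        ShuffleSpec(n_iterations=1, seed=9))[0]
        b = shuffle_tes(dataset.tes[:100], dataset.assembly,
                        ShuffleSpec(n_iterations=1, seed=9))[0]
        assert [t.interval for t in a] == [t.interval for t in b]

    def test_chromosome_occupancy_proportional_to_length(self, dataset):
        """Goodness-of-fit of placements against allowed-length weights
        over ten iterations."""
        iters = shuffle_tes(dataset.tes, dataset.assembly,
                            ShuffleSpec(n_iterations=10, seed=5))
        allowed = {}
        for chrom, length in dataset.assembly.chromosomes:
            gap = sum(e - s for s, e in dataset.assembly.gap_intervals(chrom))
            allowed[chrom] = length - gap
        total = sum(allowed.values())
        counts = {c: 0 for c in allowed}
        n = 0
        for it in iters:
            for t in it:
                counts[t.interval.chrom] += 1
                n += 1
        observed = np.array([counts[c] for c in sorted(allowed)])
        expected = np.array([allowed[c] / total * n for c in sorted(allowed)])
        _, p = stats.chisquare(observed, expected)
        assert p > 0.001

    def test_te_longer_than_every_segment_is_an_error(self):
        asm = GenomeAssembly("t", [("chr1", 1000)],
                             gaps=[GenomicInterval("chr1", 400, 600)])
        te = make_te(0, 500, te_id="big")
        with pytest.raises(ValueError, match="big"):
            shuffle_tes([te], asm, ShuffleSpec(n_iterations=1))


class TestPermutationCategoryTest:
    def test_extreme_configuration_is_significant(self):
        meta = default_metadata(12)
        values = {e: (5.0 if meta[e].group == "Blood" else -1.0) + 0.01 * i
                  for i, e in enumerate(sorted(meta))}
        res = permutation_category_test(values, meta, "group", seed=0)
        blood_up = [r for r in res if r.category == "Blood"
                    and r.direction == "higher"][0]
        assert blood_up.observed == 3
        assert blood_up.p_value < 0.05
        assert blood_up.q_value < 0.05

    def test_pvalues_invariant_to_value_rescaling(self):
        meta = default_metadata(12)
        rng = np.random.default_rng(1)
        base = {e: float(v) for e, v in zip(sorted(meta), rng.normal(size=12))}
        scaled = {e: 1000.0 * v + 7.0 for e, v in base.items()}
        r1 = permutation_category_test(base, meta, "group", seed=2)
        r2 = permutation_category_test(scaled, meta, "group", seed=2)
        assert [r.p_value for r in r1] == [r.p_value for r in r2]

    def test_categories_without_extremes_excluded_from_family(self):
        meta = default_metadata(12)
        values = {e: (5.0 if meta[e].group == "Blood" else -1.0)
                  for e in sorted(meta)}
        res = permutation_category_test(values, meta, "group", seed=0)
        higher = {r.category: r for r in res if r.direction == "higher"}
        assert not higher["Brain"].eligible
        assert np.isnan(higher["Brain"].q_value)

    def test_bh_monotone_in_p(self):
        meta = default_metadata(12)
        rng = np.random.default_rng(3)
        values = {e: float(v) for e, v in zip(sorted(meta), rng.normal(size=12))}
        res = permutation_category_test(values, meta, "group", seed=3)
        fam = sorted((r for r in res if r.eligible), key=lambda r: r.p_value)
        qs = [r.q_value for r in fam]
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in fam)

    def test_type_one_error_calibrated(self):
        """Empirical false-positive rate at alpha = 0.05 over many null
        datasets stays at or below 0.07."""
        meta = default_metadata(12)
        rng = np.random.default_rng(42)
        n_tests = n_sig = 0
        for i in range(60):
            values = {e: float(v)
                      for e, v in zip(sorted(meta), rng.normal(size=12))}
            for r in permutation_category_test(values, meta, "group",
                                               n_perm=500, seed=i):
                n_tests += 1
                n_sig += r.p_value < 0.05
        assert n_sig / n_tests <= 0.07


class TestPreferentialEnrichment:
    def test_planted_blood_subfamily_detected(self, dataset, tensor):
        res = preferential_enrichment_test(tensor, dataset.metadata,
                                           scheme="group", seed=0)
        hit = res[(res.subfamily == "SINE1_sim") & (res.state == "7_Enh")
                  & (res.category == "Blood")]
        assert len(hit) == 1 and bool(hit.significant.iloc[0])
        others = res[(res.subfamily == "SINE1_sim") & (res.state == "7_Enh")
                     & (res.category != "Blood")]
        assert not others.significant.any()

    def test_unenriched_combinations_absent_from_family(self, tensor, dataset):
        res = preferential_enrichment_test(tensor, dataset.metadata,
                                           scheme="group", seed=0)
        enriched_pairs = set(map(tuple, tensor[tensor.enriched]
                                 [["subfamily", "state"]].drop_duplicates()
                                 .to_numpy()))
        assert set(map(tuple, res[["subfamily", "state"]].drop_duplicates()
                       .to_numpy())) <= enriched_pairs

    def test_repressed_states_excluded(self, dataset, tensor):
        res = preferential_enrichment_test(tensor, dataset.metadata,
                                           scheme="group", seed=0)
        assert "9_Het" not in set(res.state)  # LTR2_sim is planted in 9_Het


class TestAssociationStats:
    def test_perfect_association(self):
        chi2, p, v = association_stats([[10, 0], [0, 10]])
        assert v == pytest.approx(1.0)

    def test_closed_form_2x2(self):
        chi2, p, v = association_stats([[30, 10], [10, 30]])
        assert chi2 == pytest.approx(20.0)
        assert v == pytest.approx(0.5)

    def test_independence(self):
        chi2, p, v = association_stats([[20, 20], [20, 20]])
        assert chi2 == pytest.approx(0.0)
        assert v == pytest.approx(0.0)

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            chi2, p, v = association_stats([[10, 0, 5], [8, 0, 7]])
        assert 0.0 <= v <= 1.0

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            association_stats([[1, 2]])
        with pytest.raises(ValueError):
            association_stats([[-1, 2], [3, 4]])
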