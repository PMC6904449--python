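import numpy as np
import pytest

from teprofiler.annotate import StateCallMatrix
from teprofiler.conservation import (
    conservation_tables,
    fit_age_trend,
    pair_orthologs,
    planted_cramers_v,
    tissue_specific_conservation,
    tissue_specific_tes,
)
from teprofiler.core import GenomicInterval
from teprofiler.simulate import simulate_ortholog_species

from conftest import make_te


class TestAgeTrends:
    def test_planted_decay_gives_negative_logistic_coefficient(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(0.0, 0.6, size=2000)
        p = 1.0 / (1.0 + np.exp(-(1.5 - 6.0 * ages)))
        y = (rng.random(2000) < p).astype(float)
        fit = fit_age_trend(ages, y, binary=True)
        assert fit.coef < 0
        assert fit.coef_pvalue < 0.01

    def test_constant_response_gives_flat_smooth(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(0.0, 0.6, size=500)
        fit = fit_age_trend(ages, np.full(500, 0.4))
        grid = np.linspace(0.05, 0.55, 20)
        assert np.allclose(fit.predict(grid), 0.4, atol=1e-6)

    def test_turning_point_recovered(self):
        """A rise-then-fall response is reproduced with its maximum near
        the planted turning point."""
        rng = np.random.default_rng(2)
        ages = rng.uniform(0.0, 0.6, size=4000)
        signal = np.exp(-((ages - 0.3) ** 2) / 0.02)
        y = signal + rng.normal(0, 0.1, size=4000)
        fit = fit_age_trend(ages, y)
        grid = np.linspace(0.02, 0.58, 200)
        peak = grid[np.argmax(fit.predict(grid))]
        assert abs(peak - 0.3) < 0.05

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_age_trend(np.arange(10) / 10.0, np.arange(10.0))

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_age_trend(np.full(200, 0.1), np.random.default_rng(0).normal(size=200))


class TestPairOrthologs:
    def test_overlap_and_subfamily_rules(self):
        src = make_te(1000, 1100, subfamily="S1", te_id="a")
        targets = [
            make_te(150, 300, subfamily="S1", te_id="t_same"),
            make_te(150, 300, subfamily="S2", te_id="t_other"),
            make_te(400, 500, subfamily="S1", te_id="t_far"),
        ]
        lifted = [("a", GenomicInterval("chr1", 100, 200))]
        pairs = pair_orthologs(lifted, [src], targets)
        assert [p.target_id for p in pairs] == ["t_same"]

    def test_one_pair_per_overlapping_target(self):
        src = make_te(1000, 1400, subfamily="S1", te_id="a")
        targets = [
            make_te(100, 220, subfamily="S1", te_id="t1"),
            make_te(250, 380, subfamily="S1", te_id="t2"),
        ]
        lifted = [("a", GenomicInterval("chr1", 100, 400))]
        pairs = pair_orthologs(lifted, [src], targets)
        assert {p.target_id for p in pairs} == {"t1", "t2"}

    def test_unknown_source_id_rejected(self):
        with pytest.raises(KeyError):
            pair_orthologs([("ghost", GenomicInterval("chr1", 0, 100))],
                           [], [])

    def test_planted_ortholog_map_recalled_exactly(self, dataset):
        sp2 = simulate_ortholog_species(dataset, 0.5, seed=1, n_epigenomes=1)
        pairs = pair_orthologs(sp2.lifted, dataset.tes, sp2.tes)
        found = {(p.source_id, p.target_id) for p in pairs}
        planted = set(dataset.ground_truth.ortholog_map.items())
        assert planted <= found  # recall 1.0 on the planted map


class TestConservation:
    @pytest.fixture(scope="session")
    def sweep(self, dataset):
        out = {}
        for c in (0.0, 0.5, 1.0):
            sp2 = simulate_ortholog_species(dataset, c, seed=2, n_epigenomes=2)
            pairs = pair_orthologs(sp2.lifted, dataset.tes, sp2.tes)
            tables = conservation_tables(
                pairs, {t.id: t for t in dataset.tes},
                {t.id: t for t in sp2.tes}, dataset.segmentations,
                sp2.segmentations, sp2.epigenome_pairs,
                dataset.methylation, sp2.methylation)
            out[c] = tables
        return out

    def test_full_conservation_is_diagonal(self, sweep):
        ch = sweep[1.0][sweep[1.0].analysis == "chromhmm"]
        assert ch.cramers_v.min() > 0.95

    def test_v_monotone_in_conservation_prob(self, sweep):
        for analysis in ("chromhmm", "methylation_2x2"):
            vs = [sweep[c][sweep[c].analysis == analysis].cramers_v.mean()
                  for c in (0.0, 0.5, 1.0)]
            assert vs[0] < vs[1] < vs[2]

    def test_closed_form_matches_at_intermediate_prob(self, dataset, sweep):
        p = np.array([dataset.config.state_freqs[s]
                      for s in dataset.config.state_alphabet])
        expected = planted_cramers_v(0.5, p)
        assert expected == pytest.approx(0.5, abs=1e-12)
        measured = sweep[0.5][sweep[0.5].analysis == "chromhmm"].cramers_v.mean()
        assert measured == pytest.approx(expected, abs=0.07)

    def test_invalid_probability_rejected(self, dataset):
        with pytest.raises(ValueError):
            simulate_ortholog_species(dataset, 1.5)

    def test_lift_rate_controls_table_size(self, dataset):
        sp2 = simulate_ortholog_species(dataset, 0.5, liftover_rate=0.5,
                                        target_rate=1.0, seed=3,
                                        n_epigenomes=1)
        frac = len(sp2.lifted) / len(dataset.tes)
        assert abs(frac - 0.5) < 0.05

    def test_ortholog_map_injective(self, dataset):
        sp2 = simulate_ortholog_species(dataset, 0.5, seed=4, n_epigenomes=1)
        targets = list(dataset.ground_truth.ortholog_map.values())
        assert len(targets) == len(set(targets))


class TestTissueSpecificity:
    def _matrix(self):
        m = StateCallMatrix(
            ["t1", "t2", "t3"],
            ["b1", "b2", "h1", "h2", "l1", "l2"], ("A", "B"))
        # t1: state A in both brain epigenomes only (2 overall)
        m.membership[0, 0, 0] = m.membership[0, 1, 0] = True
        # t2: state A in 5 epigenomes overall
        m.membership[1, :5, 0] = True
        # t3: A in 2 brain + 2 heart (4 overall)
        m.membership[2, 0:4, 0] = True
        return m

    def _tissues(self):
        return {"b1": "brain", "b2": "brain", "h1": "heart", "h2": "heart",
                "l1": "lung", "l2": "lung"}

    def test_specificity_rule(self):
        spec = tissue_specific_tes(self._matrix(), self._tissues(), "A")
        assert "t1" in spec["brain"]
        assert "t2" not in spec["brain"]          # 5 epigenomes overall: capped
        assert "t3" in spec["brain"] and "t3" in spec["heart"]  # multi-tissue

    def test_exactly_two_reading(self):
        m = self._matrix()
        m.membership[0, 2, 0] = False
        spec = tissue_specific_tes(m, self._tissues(), "A", exactly=True)
        assert "t1" in spec["brain"]
        assert "t3" in spec["brain"]

    def test_transfer_fraction(self):
        m1 = self._matrix()
        m2 = self._matrix()
        pairs = pair_orthologs(
            [("t1", GenomicInterval("chr1", 100, 200)),
             ("t3", GenomicInterval("chr1", 400, 500))],
            [make_te(100, 200, te_id="t1"), make_te(400, 500, te_id="t3")],
            [make_te(150, 250, te_id="t1"), make_te(450, 550, te_id="t3")])
        out = tissue_specific_conservation(
            m1, m2, self._tissues(), self._tissues(), pairs, "A")
        brain = out[out.tissue == "brain"].iloc[0]
        assert brain.n_tissue_specific == 2
        assert brain.transfer_fraction == pytest.approx(1.0)
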