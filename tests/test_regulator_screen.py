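import numpy as np
import pytest
from scipy import stats

from agingtx.genome_io import GeneModel, GeneSet, Peak, PeakSet
from agingtx.regulator_screen import (
    EnrichmentResult,
    ScreenError,
    ScreenParams,
    bonferroni_threshold,
    complexity_filter,
    compute_complexity,
    enrichment_test,
    intersect_replicates,
    map_peaks_to_genes,
    panel_complexity,
    run_screen,
)


def _ps(factor, stage, peaks, rep=1):
    return PeakSet(factor, stage, rep, peaks)


class TestIntersectReplicates:
    def test_identical_peak_kept(self):
        p = Peak("chrI", 100, 200, 150, 5.0)
        out = intersect_replicates(
            _ps("TF", "L1", [p]), _ps("TF", "L1", [p], rep=2)
        )
        assert out.peaks == [p]

    def test_rep1_only_peak_dropped(self):
        out = intersect_replicates(
            _ps("TF", "L1", [Peak("chrI", 100, 200, 150)]),
            _ps("TF", "L1", [Peak("chrI", 500, 600, 550)], rep=2),
        )
        assert len(out) == 0

    def test_one_bp_overlap_kept_as_union(self):
        out = intersect_replicates(
            _ps("TF", "L1", [Peak("chrI", 100, 200, 150, 1.0)]),
            _ps("TF", "L1", [Peak("chrI", 199, 300, 250, 9.0)], rep=2),
        )
        (peak,) = out.peaks
        assert (peak.start, peak.end) == (100, 300)
        # higher-scoring rep2 peak donates the summit
        assert peak.summit == 250

    def test_score_tie_prefers_rep1_summit(self):
        out = intersect_replicates(
            _ps("TF", "L1", [Peak("chrI", 100, 200, 150, 5.0)]),
            _ps("TF", "L1", [Peak("chrI", 150, 250, 220, 5.0)], rep=2),
        )
        assert out.peaks[0].summit == 150

    def test_metadata_mismatch_errors(self):
        with pytest.raises(ScreenError, match="mismatch"):
            intersect_replicates(
                _ps("TF1", "L1", []), _ps("TF2", "L1", [], rep=2)
            )


class TestComplexity:
    def test_distinct_factor_semantics(self):
        focal = _ps("A", "L1", [Peak("chrI", 100, 200, 150)])
        panel = [
            focal,
            _ps("B", "L1", [Peak("chrI", 150, 250, 200),
                            Peak("chrI", 90, 160, 120),
                            Peak("chrI", 180, 210, 190)]),
            _ps("C", "L1", [Peak("chrI", 199, 300, 250)]),
            _ps("D", "L1", [Peak("chrI", 5000, 5100, 5050)]),
            _ps("E", "L4", [Peak("chrI", 100, 200, 150)]),  # wrong stage
        ]
        assert compute_complexity(panel, focal) == [2]  # B once, C once

    def test_isolated_peak_scores_zero(self):
        focal = _ps("A", "L1", [Peak("chrI", 10, 20, 15)])
        panel = [focal, _ps("B", "L1", [Peak("chrI", 100, 200, 150)])]
        assert compute_complexity(panel, focal) == [0]

    def test_missing_focal_warns_but_proceeds(self):
        focal = _ps("A", "L1", [Peak("chrI", 10, 20, 15)])
        with pytest.warns(UserWarning, match="absent"):
            scores = compute_complexity(
                [_ps("B", "L1", [Peak("chrI", 12, 30, 20)])], focal
            )
        assert scores == [1]

    def test_panel_matches_per_dataset_reference(self, rng):
        # random panel; the vectorized panel scorer must agree with the
        # intervaltree reference for every dataset
        panel = []
        for f in range(6):
            peaks = []
            for _ in range(40):
                s = int(rng.integers(0, 5000))
                peaks.append(Peak("chrI", s, s + 80, s + 40))
            panel.append(_ps(f"F{f}", "L1", sorted(
                peaks, key=lambda p: p.start)))
        fast = panel_complexity(panel)
        for ds, scores in zip(panel, fast):
            assert scores == compute_complexity(panel, ds)

    def test_filter_is_strict_and_idempotent(self):
        params = ScreenParams(complexity_max=8)
        peaks = _ps("A", "L1", [Peak("chrI", i * 100, i * 100 + 50,
                                     i * 100 + 25) for i in range(4)])
        scores = [7, 8, 0, 11]
        kept = complexity_filter(peaks, scores, params)
        assert [p.start for p in kept.peaks] == [0, 200]
        # filtering the survivors again with their scores changes nothing
        survivor_scores = [s for s in scores if s < 8]
        again = complexity_filter(kept, survivor_scores, params)
        assert again.peaks == kept.peaks


class TestMapPeaksToGenes:
    params = ScreenParams()

    def _map(self, summits, genes):
        peaks = [Peak("chrI", s - 10, s + 10, s) for s in summits]
        return map_peaks_to_genes(
            _ps("TF", "L1", peaks), genes, self.params
        ).members

    def test_plus_strand_upstream_window(self, tiny_genes):
        # g1: + strand, TSS 10,000, window [5000, 10000)
        assert "g1" in self._map([5200], tiny_genes)
        assert "g1" in self._map([9999], tiny_genes)
        assert "g1" not in self._map([4999], tiny_genes)  # 5001 bp upstream

    def test_minus_strand_window_and_body(self):
        genes = [GeneModel("gm", "chrI", 2000, 4000, "-")]
        params = ScreenParams()
        # window [4000, 9000)
        for summit, expected in [(8999, True), (9000, False), (3500, True)]:
            peaks = _ps("TF", "L1", [Peak("chrI", summit - 10, summit + 10,
                                          summit)])
            got = "gm" in map_peaks_to_genes(peaks, genes, params).members
            assert got is expected, summit

    def test_gene_body_assignment(self, tiny_genes):
        assert "g1" in self._map([11_000], tiny_genes)

    def test_summit_not_interval_decides(self, tiny_genes):
        # interval overlaps g1's window but summit is outside it
        peaks = _ps("TF", "L1", [Peak("chrI", 9900, 10050, 10030)])
        # summit 10030 is in the gene body, so assigned via body...
        assert "g1" in map_peaks_to_genes(peaks, tiny_genes,
                                          self.params).members
        peaks2 = _ps("TF", "L1", [Peak("chrI", 4900, 5100, 4950)])
        assert "g1" not in map_peaks_to_genes(peaks2, tiny_genes,
                                              self.params).members

    def test_unknown_chrom_warns(self, tiny_genes):
        peaks = _ps("TF", "L1", [Peak("chrMT", 100, 200, 150)])
        with pytest.warns(UserWarning, match="unknown chromosome"):
            out = map_peaks_to_genes(peaks, tiny_genes, self.params)
        assert len(out) == 0


def _sets(overlap, n_targets, n_set, n_universe):
    universe = [f"g{i}" for i in range(n_universe)]
    targets = universe[:n_targets]
    age = universe[n_targets - overlap:n_targets - overlap + n_set]
    return (
        GeneSet("t", frozenset(targets)),
        GeneSet("a", frozenset(age)),
        GeneSet("u", frozenset(universe)),
    )


class TestEnrichment:
    def test_published_screen_arithmetic(self):
        # 276 of 2484 targets in a 1057-gene set over ~20,000 genes is a
        # 2.1-fold enrichment
        t, a, u = _sets(276, 2484, 1057, 20_000)
        res = enrichment_test(t, a, u)
        assert res.fold == pytest.approx(2.1, abs=0.005)
        assert res.expected_overlap == pytest.approx(2484 * 1057 / 20_000)
        assert res.p < 1e-40

    def test_matches_scipy_contingency_oracle(self, rng):
        for _ in range(1000):
            n_universe = int(rng.integers(50, 2000))
            n_targets = int(rng.integers(1, n_universe))
            n_set = int(rng.integers(1, n_universe))
            overlap = int(rng.integers(
                max(0, n_targets + n_set - n_universe),
                min(n_targets, n_set) + 1,
            ))
            t, a, u = _sets(overlap, n_targets, n_set, n_universe)
            res = enrichment_test(t, a, u)
            table = np.array(
                [
                    [overlap, n_targets - overlap],
                    [n_set - overlap, n_universe - n_targets - n_set + overlap],
                ]
            )
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                assert res.chi2 == 0.0 and res.p == 1.0
                continue
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            assert res.chi2 == pytest.approx(chi2, rel=1e-10, abs=1e-12)
            assert res.p == pytest.approx(p, rel=1e-8, abs=1e-300)

    def test_small_table_hand_check(self):
        t, a, u = _sets(5, 10, 20, 100)
        res = enrichment_test(t, a, u)
        assert res.expected_overlap == pytest.approx(2.0)
        assert res.fold == pytest.approx(2.5)
        chi2, _, _, _ = stats.chi2_contingency(
            [[5, 5], [15, 75]], correction=False
        )
        assert res.chi2 == pytest.approx(chi2)

    def test_overlap_at_expectation_is_null(self):
        t, a, u = _sets(2, 10, 20, 100)
        res = enrichment_test(t, a, u)
        assert res.fold == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_low_expected_flagged(self):
        t, a, u = _sets(2, 3, 4, 1000)
        assert enrichment_test(t, a, u).low_expected

    def test_empty_universe_errors(self):
        with pytest.raises(ScreenError, match="universe"):
            enrichment_test(
                GeneSet("t", frozenset()),
                GeneSet("a", frozenset()),
                GeneSet("u", frozenset()),
            )


class TestRunScreen:
    def test_bonferroni_threshold_for_published_family(self):
        assert bonferroni_threshold(99, 0.05) == pytest.approx(
            5.05e-4, rel=1e-3
        )

    def test_cutoff_logic_fold_vs_p(self, small_annotation):
        # a dataset can clear Bonferroni yet fail the joint screen cutoff
        res = EnrichmentResult(
            "d", 10, 10, 5, 100, 3.5, 1.4, 40.0, 1e-9
        )
        params = ScreenParams()
        res.passes_bonferroni = res.p < bonferroni_threshold(99)
        res.passes_screen = (
            res.fold >= params.fold_cutoff and res.p < params.p_cutoff
        )
        assert res.passes_bonferroni and not res.passes_screen

    def test_zero_datasets_errors(self, small_annotation):
        _, genes, _ = small_annotation
        with pytest.raises(ScreenError):
            run_screen([], GeneSet("a", frozenset({"g00001"})), genes)

    def test_planted_factor_ranks_first(self):
        from agingtx.synthetic_data import (
            SimulationConfig,
            simulate_annotation,
            simulate_chip_datasets,
        )

        cfg = SimulationConfig(
            n_genes=2000,
            n_factors=20,
            n_datasets=20,
            planted_enrichment_fold=2.5,
            seed=17,
        )
        genes, sizes = simulate_annotation(cfg)
        datasets, age_set, truth = simulate_chip_datasets(genes, cfg, sizes)
        merged = [intersect_replicates(a, b) for a, b in datasets]
        results = run_screen(merged, age_set, genes)
        assert results[0].dataset_id == "TF00.L1"
        assert results[0].passes_screen
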