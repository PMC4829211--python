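import itertools
import math

import numpy as np
import pandas as pd
import pytest

from agingtx.genome_io import CountMatrix, SampleDesign
from agingtx.rankprod_de import (
    PfpResult,
    RankProdError,
    RankProdParams,
    RankProductResult,
    call_de,
    normalize_fractions,
    permutation_pfp,
    rank_product,
    rank_product_de,
    stage_stats,
)
from agingtx.synthetic_data import (
    SimulationConfig,
    make_de_design,
    simulate_annotation,
    simulate_counts,
)


def _design(n_treated, n_control, stage="L1"):
    names = [f"t{i}" for i in range(n_treated)] + [
        f"c{i}" for i in range(n_control)
    ]
    df = pd.DataFrame(
        {
            "condition": ["treated"] * n_treated + ["control"] * n_control,
            "stage_or_timepoint": [stage] * (n_treated + n_control),
            "replicate": list(range(1, n_treated + 1))
            + list(range(1, n_control + 1)),
        },
        index=pd.Index(names, name="sample_id"),
    )
    return SampleDesign(df)


class TestNormalize:
    def test_fractions_without_pseudocount(self):
        cm = CountMatrix(pd.DataFrame({"s1": [10, 30, 60]}, index=list("abc")))
        norm = normalize_fractions(cm, pseudocount_reads=0)
        assert norm["s1"].tolist() == pytest.approx([0.1, 0.3, 0.6])

    def test_columns_sum_to_one(self, toy_counts):
        cm, _ = toy_counts
        norm = normalize_fractions(cm)
        assert np.allclose(norm.sum(axis=0), 1.0, atol=1e-9)

    def test_pseudocount_makes_zero_counts_positive(self):
        cm = CountMatrix(pd.DataFrame({"s1": [0, 10]}, index=["a", "b"]))
        norm = normalize_fractions(cm, pseudocount_reads=0.5)
        assert (norm > 0).all().all()

    def test_all_zero_sample_errors(self):
        cm = CountMatrix(pd.DataFrame({"s1": [0, 0]}, index=["a", "b"]))
        with pytest.raises(RankProdError, match="all-zero"):
            normalize_fractions(cm)


class TestRankProduct:
    def test_consistent_extreme_gene_has_rp_one(self):
        # gene 'a' most down-regulated in every comparison
        norm = pd.DataFrame(
            {
                "t0": [0.01, 0.4, 0.59],
                "t1": [0.02, 0.38, 0.60],
                "c0": [0.30, 0.35, 0.35],
                "c1": [0.28, 0.36, 0.36],
            },
            index=list("abc"),
        )
        rp = rank_product(norm, _design(2, 2), ("treated", "control"), "L1")
        assert rp.rp_down[0] == pytest.approx(1.0)
        assert rp.ranks_down.shape == (3, 4)

    def test_geometric_mean_closed_form(self):
        ranks = np.array([[2.0, 3.0, 6.0]])
        from agingtx.rankprod_de import _geometric_mean_ranks

        assert _geometric_mean_ranks(ranks)[0] == pytest.approx(36 ** (1 / 3))

    def test_ties_get_average_ranks(self):
        # genes a and b have identical folds in the single comparison
        norm = pd.DataFrame(
            {"t0": [0.2, 0.2, 0.6], "c0": [0.3, 0.3, 0.4]}, index=list("abc")
        )
        rp = rank_product(norm, _design(1, 1), ("treated", "control"), "L1")
        assert rp.ranks_down[0, 0] == rp.ranks_down[1, 0] == 1.5

    def test_directions_are_reversed_ranks_without_ties(self, rng):
        norm = pd.DataFrame(
            {
                "t0": rng.dirichlet(np.ones(20)),
                "c0": rng.dirichlet(np.ones(20)),
            },
            index=[f"g{i}" for i in range(20)],
        )
        rp = rank_product(norm, _design(1, 1), ("treated", "control"), "L1")
        n = 20
        assert np.allclose(rp.ranks_down + rp.ranks_up, n + 1)
        assert rp.rp_down.min() >= 1 and rp.rp_down.max() <= n

    def test_empty_group_errors(self):
        norm = pd.DataFrame({"c0": [0.5, 0.5]}, index=["a", "b"])
        with pytest.raises(RankProdError, match="no samples"):
            rank_product(norm, _design(0, 1), ("treated", "control"), "L1")


def _brute_force_pfp(ranks: np.ndarray):
    """Independent enumeration oracle: all within-comparison label
    permutations, p and pfp computed from first principles."""
    n, k = ranks.shape
    rp_obs = np.prod(ranks, axis=1) ** (1.0 / k)
    null_rps = []
    for combo in itertools.product(
        itertools.permutations(range(n)), repeat=k
    ):
        for g in range(n):
            prod = 1.0
            for j in range(k):
                prod *= ranks[combo[j][g], j]
            null_rps.append(prod ** (1.0 / k))
    null_rps = np.array(null_rps)
    n_perm = math.factorial(n) ** k
    p = np.empty(n)
    pfp = np.empty(n)
    order = np.argsort(np.argsort(rp_obs)) + 1  # 1-based ranks, no ties here
    for g in range(n):
        count = float((null_rps <= rp_obs[g] + 1e-12).sum())
        p[g] = (count + 1) / (n * n_perm + 1)
        pfp[g] = (count / n_perm) / order[g]
    return p, pfp


class TestPermutationPfp:
    def test_exhaustive_matches_enumeration_oracle(self):
        # 3 genes, 2 samples (1 treated vs 1 control -> 1 comparison)
        norm = pd.DataFrame(
            {"t0": [0.1, 0.3, 0.6], "c0": [0.5, 0.3, 0.2]}, index=list("abc")
        )
        rp = rank_product(norm, _design(1, 1), ("treated", "control"), "L1")
        res = permutation_pfp(rp, exhaustive=True)
        p_exp, pfp_exp = _brute_force_pfp(rp.ranks_down)
        assert res.p_down == pytest.approx(p_exp)
        assert res.pfp_down == pytest.approx(pfp_exp)
        p_exp_up, pfp_exp_up = _brute_force_pfp(rp.ranks_up)
        assert res.p_up == pytest.approx(p_exp_up)
        assert res.pfp_up == pytest.approx(pfp_exp_up)

    def test_null_p_values_uniform_single_comparison(self, rng):
        # with one comparison the permutation p is exactly calibrated
        n = 1000
        norm = pd.DataFrame(
            {"t0": rng.dirichlet(np.ones(n)), "c0": rng.dirichlet(np.ones(n))},
            index=[f"g{i}" for i in range(n)],
        )
        rp = rank_product(norm, _design(1, 1), ("treated", "control"), "L1")
        res = permutation_pfp(rp, RankProdParams(n_permutations=100, seed=0))
        frac = float((res.p_down < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_planted_top_gene_gets_tiny_pfp(self):
        cfg = SimulationConfig(
            n_genes=1000,
            planted_down={"l1_only": 1},
            planted_up={},
            lfc_magnitude=4.0,
            nb_dispersion=0.01,
            seed=31,
        )
        genes, _ = simulate_annotation(cfg)
        design = make_de_design(cfg)
        cm, truth = simulate_counts(genes, design, cfg)
        (planted,) = truth.de_genes("down")
        norm = normalize_fractions(cm)
        rp = rank_product(norm, design, ("treated", "control"), "L1")
        res = permutation_pfp(rp, RankProdParams(n_permutations=100, seed=1))
        gi = rp.gene_ids.index(planted)
        assert rp.rp_down[gi] == pytest.approx(1.0, abs=0.6)
        assert res.pfp_down[gi] < 0.01

    def test_identical_seed_identical_pfp(self, toy_counts):
        cm, design = toy_counts
        params = RankProdParams(n_permutations=50, seed=7)
        a = rank_product_de(cm, design, "treated", "control", "L1", params)
        b = rank_product_de(cm, design, "treated", "control", "L1", params)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_permutations_errors(self, toy_counts):
        cm, design = toy_counts
        with pytest.raises(RankProdError):
            rank_product_de(
                cm, design, "treated", "control", "L1",
                RankProdParams(n_permutations=5),
            )

    def test_monotone_in_effect_size(self):
        # a stronger planted effect never worsens the planted gene's pfp
        pfps = []
        for lfc in (0.5, 1.0, 2.0, 3.0):
            cfg = SimulationConfig(
                n_genes=300,
                planted_down={"l1_only": 1},
                planted_up={},
                lfc_magnitude=lfc,
                nb_dispersion=0.01,
                seed=77,  # same base draws; only the planted effect varies
            )
            genes, _ = simulate_annotation(cfg)
            design = make_de_design(cfg)
            cm, truth = simulate_counts(genes, design, cfg)
            (planted,) = truth.de_genes("down")
            norm = normalize_fractions(cm)
            rp = rank_product(norm, design, ("treated", "control"), "L1")
            res = permutation_pfp(rp, RankProdParams(seed=5))
            pfps.append(res.pfp_down[rp.gene_ids.index(planted)])
        assert all(b <= a + 1e-9 for a, b in zip(pfps, pfps[1:]))


class TestCallDe:
    def _fake(self, pfp_down):
        n = len(pfp_down)
        rp = RankProductResult(
            gene_ids=[f"g{i}" for i in range(n)],
            comparisons=[("t", "c")],
            ranks_down=np.ones((n, 1)),
            ranks_up=np.ones((n, 1)),
            rp_down=np.arange(1, n + 1, dtype=float),
            rp_up=np.arange(n, 0, -1, dtype=float),
            mean_log2_fc=-np.ones(n),
        )
        pfp = PfpResult(
            p_down=np.full(n, 0.5),
            p_up=np.full(n, 0.5),
            pfp_down=np.array(pfp_down),
            pfp_up=np.full(n, 2.0),
        )
        return rp, pfp

    def test_cutoff_selects_genes(self):
        rp, pfp = self._fake([0.01, 0.2, 0.05])
        table = call_de(rp, pfp, RankProdParams(fdr_cutoff=0.10))
        called = set(table.loc[table.called == "down", "gene_id"])
        assert called == {"g0", "g2"}

    def test_tiny_cutoff_calls_nothing(self):
        rp, pfp = self._fake([0.01, 0.2, 0.05])
        table = call_de(rp, pfp, RankProdParams(fdr_cutoff=1e-9))
        assert (table.called == "none").all()

    def test_recovery_on_stage_l1_preset(self):
        # preset shaped like the L1 RNAi experiment: 153 down + 9 up
        # planted; paired comparisons keep the permutation null exact
        # (all-pairs comparisons share samples and are anti-conservative)
        from agingtx.synthetic_data import l1_experiment_config

        sens, fdrs = [], []
        for seed in range(3):
            cfg = l1_experiment_config(seed=100 + seed)
            genes, _ = simulate_annotation(cfg)
            design = make_de_design(cfg)
            cm, truth = simulate_counts(genes, design, cfg)
            table = rank_product_de(
                cm, design, "treated", "control", "L1",
                RankProdParams(n_permutations=100, seed=seed, paired=True),
            )
            called = table.loc[table.called != "none"]
            called_set = set(called.gene_id)
            planted = truth.de_genes()
            tp = len(called_set & planted)
            sens.append(tp / len(planted))
            fdrs.append(
                (len(called_set) - tp) / max(len(called_set), 1)
            )
            # direction split leans heavily downward, as planted
            n_down = (called.called == "down").sum()
            assert n_down > 5 * max((called.called == "up").sum(), 1)
        assert np.mean(sens) >= 0.8
        assert np.mean(fdrs) <= 0.15

    def test_stage_stats_direction_and_membership(self, toy_counts):
        cm, design = toy_counts
        table = rank_product_de(
            cm, design, "treated", "control", "L1",
            RankProdParams(n_permutations=50, seed=1),
        )
        st = stage_stats(table)
        assert set(st.columns) == {"log2_fc", "p", "in_de_list"}
        down = table.set_index("gene_id")["mean_log2_fc"] < 0
        assert (st.loc[down.index[down], "log2_fc"] < 0).all()
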