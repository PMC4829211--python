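"""Rank-product differential expression with permutation-based pfp.

Counts are first normalized per sample as the fraction of reads assigned to
each gene (3'-tag data are insensitive to transcript length, so the
fraction of total mapped reads is the natural expression measure).  For a
treated/control contrast, a fold change is formed for every treated x
control sample pair; within each comparison, genes are ranked by fold
(ascending for down-regulation, descending for up-regulation; ties get
average ranks) and a gene's rank product (RP) is the geometric mean of its
ranks over comparisons.  Significance comes from permutations: gene labels
are independently shuffled within each comparison's fold vector, null RPs
are pooled, and each gene gets a permutation p-value and a pfp (expected
false positives at its RP divided by its rank) — the FDR-like quantity
thresholded for calling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import CountMatrix, SampleDesign


class RankProdError(ValueError):
    pass


@dataclass
class RankProdParams:
    fdr_cutoff: float = 0.10
    n_permutations: int = 100
    pseudocount_reads: float = 0.5
    seed: int = 0
    paired: bool = False  # index-paired replicates instead of all pairs

    def validate(self) -> None:
        if not (0 < self.fdr_cutoff < 1):
            raise RankProdError("fdr_cutoff must be in (0, 1)")
        if self.n_permutations < 10:
            raise RankProdError("n_permutations must be >= 10")


@dataclass
class RankProductResult:
    """Observed ranks and rank products for one contrast."""

    gene_ids: list[str]
    comparisons: list[tuple[str, str]]  # (treated sample, control sample)
    ranks_down: np.ndarray  # genes x comparisons, rank 1 = most down
    ranks_up: np.ndarray
    rp_down: np.ndarray
    rp_up: np.ndarray
    mean_log2_fc: np.ndarray


@dataclass
class PfpResult:
    p_down: np.ndarray
    p_up: np.ndarray
    pfp_down: np.ndarray
    pfp_up: np.ndarray
    n_permutations: int = 0
    exhaustive: bool = False


# ---------------------------------------------------------------------------


def normalize_fractions(
    counts: CountMatrix, pseudocount_reads: float = 0.5
) -> pd.DataFrame:
    """Per-sample fractions: (count + pseudocount) / sum(count + pseudocount).

    Columns sum to 1; with a positive pseudocount every fraction is
    strictly positive.
    """
    raw = counts.counts
    if (raw.sum(axis=0) == 0).any():
        zero = raw.columns[raw.sum(axis=0) == 0].tolist()
        raise RankProdError(f"all-zero sample(s): {zero}")
    shifted = raw.astype(float) + pseudocount_reads
    return shifted / shifted.sum(axis=0)


def _geometric_mean_ranks(ranks: np.ndarray) -> np.ndarray:
    return np.exp(np.mean(np.log(ranks), axis=-1))


def rank_product(
    norm: pd.DataFrame,
    design: SampleDesign,
    condition_pair: tuple[str, str],
    stage: str | None = None,
    paired: bool = False,
) -> RankProductResult:
    """Observed rank products for a (treated, control) contrast.

    Comparisons are all treated x control sample pairs (or index-paired
    replicates with ``paired=True``).  Fold = fraction_treated /
    fraction_control; ranks use average tie-handling.
    """
    treated_label, control_label = condition_pair
    treated = design.select(treated_label, stage)
    control = design.select(control_label, stage)
    if not treated or not control:
        raise RankProdError(
            f"no samples for contrast {treated_label!r} vs {control_label!r}"
            + (f" at {stage!r}" if stage else "")
        )
    if paired:
        if len(treated) != len(control):
            raise RankProdError("paired mode requires equal replicate counts")
        pairs = list(zip(treated, control))
    else:
        pairs = [(t, c) for t in treated for c in control]

    folds = np.column_stack(
        [norm[t].to_numpy() / norm[c].to_numpy() for t, c in pairs]
    )
    ranks_down = np.column_stack(
        [stats.rankdata(folds[:, k], method="average")
         for k in range(folds.shape[1])]
    )
    ranks_up = np.column_stack(
        [stats.rankdata(-folds[:, k], method="average")
         for k in range(folds.shape[1])]
    )
    return RankProductResult(
        gene_ids=list(norm.index),
        comparisons=pairs,
        ranks_down=ranks_down,
        ranks_up=ranks_up,
        rp_down=_geometric_mean_ranks(ranks_down),
        rp_up=_geometric_mean_ranks(ranks_up),
        mean_log2_fc=np.log2(folds).mean(axis=1),
    )


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------


def _pooled_null_counts(
    null_rp: np.ndarray, observed_rp: np.ndarray
) -> np.ndarray:
    """count(null RP <= observed RP_g) for each gene, pooling all null
    values."""
    pool = np.sort(null_rp.ravel())
    return np.searchsorted(pool, observed_rp, side="right").astype(float)


def _p_and_pfp(
    observed_rp: np.ndarray, null_rp: np.ndarray, n_perm: int
) -> tuple[np.ndarray, np.ndarray]:
    n_genes = observed_rp.shape[0]
    counts = _pooled_null_counts(null_rp, observed_rp)
    p = (counts + 1.0) / (n_genes * n_perm + 1.0)
    gene_rank = stats.rankdata(observed_rp, method="average")
    pfp = (counts / n_perm) / gene_rank
    return p, pfp


def _permuted_null(
    ranks: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null RPs from shuffling each comparison's rank column independently,
    ``n_perm`` times.  Returns (n_perm, n_genes)."""
    n_genes, k = ranks.shape
    idx = np.argsort(rng.random((n_perm, n_genes, k)), axis=1)
    null_ranks = np.take_along_axis(
        np.broadcast_to(ranks, (n_perm, n_genes, k)), idx, axis=1
    )
    return _geometric_mean_ranks(null_ranks)


def _exhaustive_null(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Enumerate every combination of within-comparison label permutations.

    Feasible only for tiny problems (n_genes! ** n_comparisons bounded).
    Returns (null RPs stacked as (n_combos, n_genes), n_combos).
    """
    n_genes, k = ranks.shape
    n_combos = math.factorial(n_genes) ** k
    if n_combos * n_genes > 2_000_000:
        raise RankProdError("exhaustive enumeration infeasible at this size")
    perms = list(itertools.permutations(range(n_genes)))
    rows = []
    for combo in itertools.product(perms, repeat=k):
        null = np.column_stack(
            [ranks[list(combo[j]), j] for j in range(k)]
        )
        rows.append(_geometric_mean_ranks(null))
    return np.array(rows), n_combos


def permutation_pfp(
    rp_observed: RankProductResult,
    params: RankProdParams | None = None,
    exhaustive: bool = False,
) -> PfpResult:
    """Permutation p-values and pfp for both directions.

    p(g) = (#{null RP <= RP_g} + 1) / (n_genes * n_perm + 1);
    pfp(g) = (#{null RP <= RP_g} / n_perm) / rank(RP_g).
    With ``exhaustive=True`` every within-comparison permutation is
    enumerated instead of sampled (tiny problems only).
    """
    params = params or RankProdParams()
    if exhaustive:
        null_down, n_eff = _exhaustive_null(rp_observed.ranks_down)
        null_up, _ = _exhaustive_null(rp_observed.ranks_up)
        p_down, pfp_down = _p_and_pfp(rp_observed.rp_down, null_down, n_eff)
        p_up, pfp_up = _p_and_pfp(rp_observed.rp_up, null_up, n_eff)
        return PfpResult(p_down, p_up, pfp_down, pfp_up, n_eff, True)
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_perm = params.n_permutations
    null_down = _permuted_null(rp_observed.ranks_down, n_perm, rng)
    # ranks_up mirror ranks_down; reuse the same permutation stream shape
    null_up = _permuted_null(rp_observed.ranks_up, n_perm, rng)
    p_down, pfp_down = _p_and_pfp(rp_observed.rp_down, null_down, n_perm)
    p_up, pfp_up = _p_and_pfp(rp_observed.rp_up, null_up, n_perm)
    return PfpResult(p_down, p_up, pfp_down, pfp_up, n_perm, False)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------


def call_de(
    rp: RankProductResult,
    pfp: PfpResult,
    params: RankProdParams | None = None,
) -> pd.DataFrame:
    """Table of per-gene DE statistics with the FDR-cutoff call.

    called = down if pfp_down <= cutoff, up if pfp_up <= cutoff; a gene
    passing both directions gets the direction of the smaller pfp.  Rows
    are ordered by the smaller pfp, then gene id.  pfp is reported
    unclipped (it may exceed 1).
    """
    params = params or RankProdParams()
    cutoff = params.fdr_cutoff
    called = np.full(len(rp.gene_ids), "none", dtype=object)
    down = pfp.pfp_down <= cutoff
    up = pfp.pfp_up <= cutoff
    called[down] = "down"
    called[up] = "up"
    both = down & up
    called[both & (pfp.pfp_down <= pfp.pfp_up)] = "down"
    called[both & (pfp.pfp_up < pfp.pfp_down)] = "up"
    df = pd.DataFrame(
        {
            "gene_id": rp.gene_ids,
            "mean_log2_fc": rp.mean_log2_fc,
            "rp_down": rp.rp_down,
            "rp_up": rp.rp_up,
            "p_down": pfp.p_down,
            "p_up": pfp.p_up,
            "pfp_down": pfp.pfp_down,
            "pfp_up": pfp.pfp_up,
            "called": called,
        }
    )
    df["min_pfp"] = np.minimum(df["pfp_down"], df["pfp_up"])
    df = df.sort_values(["min_pfp", "gene_id"]).drop(columns="min_pfp")
    return df.reset_index(drop=True)


def rank_product_de(
    counts: CountMatrix,
    design: SampleDesign,
    treated: str,
    control: str,
    stage: str | None = None,
    params: RankProdParams | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: normalize -> rank product -> permutation pfp ->
    call at the FDR cutoff."""
    params = params or RankProdParams()
    params.validate()
    norm = normalize_fractions(counts, params.pseudocount_reads)
    rp = rank_product(norm, design, (treated, control), stage,
                      paired=params.paired)
    pfp = permutation_pfp(rp, params)
    return call_de(rp, pfp, params)


def stage_stats(de_table: pd.DataFrame) -> pd.DataFrame:
    """Per-stage statistics for cross-stage classification.

    ``p`` is the permutation p of the direction the gene moved (down when
    mean_log2_fc < 0, up otherwise); ``in_de_list`` marks FDR-called genes.
    """
    fc = de_table["mean_log2_fc"].to_numpy()
    p = np.where(fc < 0, de_table["p_down"], de_table["p_up"])
    return pd.DataFrame(
        {
            "gene_id": de_table["gene_id"],
            "log2_fc": fc,
            "p": p,
            "in_de_list": de_table["called"].to_numpy() != "none",
        }
    ).set_index("gene_id")
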