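"""ChIP-seq regulator-enrichment screen.

Per dataset (transcription factor x stage): keep replicate-consistent
peaks, drop promiscuously bound sites by complexity score, assign the
surviving summits to genes (5 kb upstream of the TSS or inside the gene
body), and test the target set for overrepresentation in an age-regulated
gene set with a 2x2 chi-square.  Datasets are ranked by p-value; the family
of tests is controlled with Bonferroni (family alpha / number of datasets
screened) and a screen cutoff combining an enrichment-fold floor with a
p-value ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .genome_io import GeneModel, GeneSet, Peak, PeakSet


class ScreenError(ValueError):
    pass


@dataclass
class ScreenParams:
    """Thresholds of the screen.

    complexity_max
        A peak is kept when fewer than this many *other* factors overlap it
        (strictly fewer; the default of 8 drops HOT sites).
    upstream_window_bp
        Size of the strand-aware upstream assignment window from the TSS.
    fold_cutoff, p_cutoff
        Joint screen cutoff on enrichment fold and chi-square p.
    family_alpha
        Family-wise error target for the Bonferroni threshold.
    """

    complexity_max: int = 8
    upstream_window_bp: int = 5000
    fold_cutoff: float = 1.5
    p_cutoff: float = 1e-5
    family_alpha: float = 0.05
    yates_correction: bool = False

    def validate(self) -> None:
        if self.complexity_max < 1:
            raise ScreenError("complexity_max must be >= 1")
        for name in ("upstream_window_bp", "fold_cutoff", "p_cutoff",
                     "family_alpha"):
            if getattr(self, name) <= 0:
                raise ScreenError(f"{name} must be positive")


@dataclass
class EnrichmentResult:
    dataset_id: str
    n_targets: int
    n_set: int
    n_overlap: int
    n_universe: int
    expected_overlap: float
    fold: float
    chi2: float
    p: float
    passes_bonferroni: bool = False
    passes_screen: bool = False
    low_expected: bool = False


# ---------------------------------------------------------------------------
# replicate intersection
# ---------------------------------------------------------------------------


def intersect_replicates(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Keep replicate-1 peaks that overlap (>= 1 bp) a replicate-2 peak.

    The retained interval is the union of the rep1 peak with every
    overlapping rep2 peak; the summit comes from the highest-scoring peak
    involved (rep1's on ties or missing scores).
    """
    if rep1.factor != rep2.factor or rep1.stage != rep2.stage:
        raise ScreenError(
            "replicate metadata mismatch: "
            f"{rep1.factor}/{rep1.stage} vs {rep2.factor}/{rep2.stage}"
        )
    trees: dict[str, IntervalTree] = {}
    for p in rep2.peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    kept: list[Peak] = []
    for p in rep1.peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        hits = [iv.data for iv in tree.overlap(p.start, p.end)]
        if not hits:
            continue
        start = min([p.start] + [h.start for h in hits])
        end = max([p.end] + [h.end for h in hits])
        best = p
        for h in hits:
            if (h.score or float("-inf")) > (best.score or float("-inf")):
                best = h
        kept.append(Peak(p.chrom, start, end, best.summit, best.score))
    return PeakSet(rep1.factor, rep1.stage, 0, kept).sorted()


# ---------------------------------------------------------------------------
# complexity
# ---------------------------------------------------------------------------


def _factor_trees(
    datasets: Sequence[PeakSet], stage: str, exclude_factor: str
) -> dict[str, list[tuple[str, IntervalTree]]]:
    """Per-chromosome list of (factor, interval tree) for stage-matched
    datasets of other factors."""
    by_chrom: dict[str, dict[str, IntervalTree]] = {}
    for ds in datasets:
        if ds.stage != stage or ds.factor == exclude_factor:
            continue
        for p in ds.peaks:
            by_chrom.setdefault(p.chrom, {}).setdefault(
                ds.factor, IntervalTree()
            ).addi(p.start, p.end)
    return {
        chrom: list(factors.items()) for chrom, factors in by_chrom.items()
    }


def compute_complexity(
    all_datasets: Sequence[PeakSet], focal: PeakSet
) -> list[int]:
    """Per-peak count of distinct *other* factors (same stage) overlapping
    by >= 1 bp.  Multiple peaks from one factor count once; the focal
    factor is never counted."""
    if not any(
        ds.factor == focal.factor and ds.stage == focal.stage
        for ds in all_datasets
    ):
        warnings.warn(
            f"focal dataset {focal.dataset_id} absent from the panel; "
            "proceeding (self is never counted)",
            stacklevel=2,
        )
    trees = _factor_trees(all_datasets, focal.stage, focal.factor)
    scores: list[int] = []
    for p in focal.peaks:
        per_chrom = trees.get(p.chrom, [])
        score = sum(
            1 for _, tree in per_chrom if tree.overlaps(p.start, p.end)
        )
        scores.append(score)
    return scores


def panel_complexity(datasets: Sequence[PeakSet]) -> list[list[int]]:
    """Complexity scores for every dataset of a panel.

    Equivalent to calling :func:`compute_complexity` per dataset, but the
    per-(stage, chromosome, factor) intervals are indexed once as sorted
    start arrays with prefix-maximum ends, so each overlap-existence query
    is a binary search.
    """
    from collections import defaultdict

    intervals: dict[tuple, list[tuple[int, int]]] = defaultdict(list)
    factors_by_stage: dict[str, set[str]] = defaultdict(set)
    for ds in datasets:
        factors_by_stage[ds.stage].add(ds.factor)
        for p in ds.peaks:
            intervals[(ds.stage, p.chrom, ds.factor)].append((p.start, p.end))
    index: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for key, ivs in intervals.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        prefmax_end = np.maximum.accumulate(np.array([e for _, e in ivs]))
        index[key] = (starts, prefmax_end)

    all_scores: list[list[int]] = []
    for ds in datasets:
        score = np.zeros(len(ds.peaks), dtype=int)
        by_chrom: dict[str, list[int]] = defaultdict(list)
        for i, p in enumerate(ds.peaks):
            by_chrom[p.chrom].append(i)
        for chrom, idxs in by_chrom.items():
            pos_idx = np.array(idxs)
            ps = np.array([ds.peaks[i].start for i in idxs])
            pe = np.array([ds.peaks[i].end for i in idxs])
            for factor in factors_by_stage[ds.stage]:
                if factor == ds.factor:
                    continue
                entry = index.get((ds.stage, chrom, factor))
                if entry is None:
                    continue
                starts, prefmax_end = entry
                # overlap iff some interval has start < peak.end and
                # end > peak.start
                pos = np.searchsorted(starts, pe, side="left")
                hit = (pos > 0) & (
                    prefmax_end[np.maximum(pos - 1, 0)] > ps
                )
                score[pos_idx[hit]] += 1
        all_scores.append(score.tolist())
    return all_scores


def complexity_filter(
    peaks: PeakSet, scores: Sequence[int], params: ScreenParams
) -> PeakSet:
    """Retain peaks with complexity score strictly below ``complexity_max``."""
    if len(scores) != len(peaks.peaks):
        raise ScreenError("scores not aligned to peaks")
    kept = [
        p for p, s in zip(peaks.peaks, scores) if s < params.complexity_max
    ]
    return PeakSet(peaks.factor, peaks.stage, peaks.replicate, kept)


# ---------------------------------------------------------------------------
# peak -> gene assignment
# ---------------------------------------------------------------------------


def gene_window_index(
    genes: Sequence[GeneModel], params: ScreenParams
) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees of assignment regions (gene body plus
    strand-aware upstream window), reusable across datasets."""
    params.validate()
    w = params.upstream_window_bp
    tree_by_chrom: dict[str, IntervalTree] = {}
    for g in genes:
        tree = tree_by_chrom.setdefault(g.chrom, IntervalTree())
        tree.addi(g.start, g.end, g.gene_id)  # gene body
        if g.strand == "+":
            lo, hi = g.tss - w, g.tss
        else:
            lo, hi = g.tss, g.tss + w
        if hi > max(lo, 0):
            tree.addi(max(lo, 0), hi, g.gene_id)
    return tree_by_chrom


def map_peaks_to_genes(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    params: ScreenParams,
    index: dict[str, IntervalTree] | None = None,
) -> GeneSet:
    """Assign peaks to genes by summit position.

    A gene is a target iff some summit lies in its strand-aware upstream
    window (``[TSS - w, TSS)`` on ``+``, ``[TSS, TSS + w)`` on ``-``) or
    inside the gene body ``[start, end)``.  One summit may hit several
    genes; the result is a deduplicated set.
    """
    tree_by_chrom = index if index is not None else gene_window_index(
        genes, params
    )
    targets: set[str] = set()
    for p in peaks.peaks:
        tree = tree_by_chrom.get(p.chrom)
        if tree is None:
            warnings.warn(
                f"peak summit on unknown chromosome {p.chrom}; ignored",
                stacklevel=2,
            )
            continue
        for iv in tree.at(p.summit):
            targets.add(iv.data)
    return GeneSet(name=f"{peaks.dataset_id}.targets", members=frozenset(targets))


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def enrichment_test(
    targets: GeneSet,
    age_set: GeneSet,
    universe: GeneSet,
    params: ScreenParams | None = None,
    dataset_id: str | None = None,
) -> EnrichmentResult:
    """2x2 chi-square (1 df) for target x age-set membership over a
    universe.  ``fold`` is observed/expected overlap; no continuity
    correction unless ``params.yates_correction``."""
    if len(universe) == 0:
        raise ScreenError("empty universe")
    yates = bool(params.yates_correction) if params is not None else False
    t = targets.members & universe.members
    s = age_set.members & universe.members
    n = len(universe)
    a = len(t & s)
    b = len(t) - a
    c = len(s) - a
    d = n - a - b - c
    expected_overlap = len(t) * len(s) / n
    table = np.array([[a, b], [c, d]], dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    exp = np.outer(row, col) / n
    low_expected = bool((exp < 5).any())
    if (row == 0).any() or (col == 0).any():
        chi2, p = 0.0, 1.0
    else:
        diff = np.abs(table - exp)
        if yates:
            diff = np.maximum(diff - 0.5, 0.0)
        chi2 = float((diff**2 / exp).sum())
        p = float(stats.chi2.sf(chi2, df=1))
    fold = a / expected_overlap if expected_overlap > 0 else float("nan")
    return EnrichmentResult(
        dataset_id=dataset_id or targets.name,
        n_targets=len(t),
        n_set=len(s),
        n_overlap=a,
        n_universe=n,
        expected_overlap=expected_overlap,
        fold=fold,
        chi2=chi2,
        p=p,
        low_expected=low_expected,
    )


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------


def bonferroni_threshold(n_datasets: int, family_alpha: float = 0.05) -> float:
    if n_datasets <= 0:
        raise ScreenError("zero datasets")
    return family_alpha / n_datasets


def run_screen(
    datasets: Sequence[PeakSet],
    age_set: GeneSet,
    genes: Sequence[GeneModel],
    params: ScreenParams | None = None,
) -> list[EnrichmentResult]:
    """Full screen over replicate-intersected datasets.

    Per dataset: complexity scoring against the stage-matched panel ->
    strict complexity filter -> summit-based target assignment ->
    enrichment test against ``age_set`` with the full annotation as the
    universe.  The Bonferroni threshold divides ``family_alpha`` by the
    number of datasets actually screened; ``passes_screen`` requires both
    the fold and p cutoffs.  Output sorted by ascending p, then descending
    fold, then dataset id.
    """
    if not datasets:
        raise ScreenError("zero datasets")
    params = params or ScreenParams()
    params.validate()
    from .genome_io import gene_universe

    universe = gene_universe(genes)
    threshold = bonferroni_threshold(len(datasets), params.family_alpha)
    all_scores = panel_complexity(datasets)
    window_index = gene_window_index(genes, params)
    results: list[EnrichmentResult] = []
    for ds, scores in zip(datasets, all_scores):
        filtered = complexity_filter(ds, scores, params)
        targets = map_peaks_to_genes(filtered, genes, params, window_index)
        res = enrichment_test(
            targets, age_set, universe, params, dataset_id=ds.dataset_id
        )
        res.passes_bonferroni = res.p < threshold
        res.passes_screen = (
            res.fold >= params.fold_cutoff and res.p < params.p_cutoff
        )
        results.append(res)
    results.sort(key=lambda r: (r.p, -r.fold, r.dataset_id))
    return results
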