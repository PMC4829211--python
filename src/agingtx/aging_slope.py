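"""Transcriptome-wide aging attenuation slope.

For each replicate, per-gene old/young log2 expression ratios are computed
in a control condition and in a test (e.g. overexpressor) condition, and
the test ratios are regressed on the control ratios by ordinary least
squares (with intercept).  A slope below 1 means age-related expression
changes are damped in the test condition.  Replicate slopes are averaged;
the 95% confidence interval and the test against slope = 1 use the t
distribution on the replicate slopes.  Variants restrict the regression to
tissue-specific gene lists or compare two independent aging programs.

Gene filtering before regression: keep genes with raw depth >= ``min_depth``
in at least one library of either condition, then drop the union over
libraries of each library's most highly expressed ``top_expr_fraction``
genes (highly expressed genes would otherwise dominate the shared-fraction
normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import CountMatrix, SampleDesign
from .rankprod_de import normalize_fractions


class SlopeError(ValueError):
    pass


@dataclass
class SlopeParams:
    min_depth: int = 10
    top_expr_fraction: float = 0.03
    pseudocount_reads: float = 0.5

    def validate(self) -> None:
        if self.min_depth < 0:
            raise SlopeError("min_depth must be >= 0")
        if not (0 <= self.top_expr_fraction < 1):
            raise SlopeError("top_expr_fraction must be in [0, 1)")


@dataclass
class SlopeFit:
    replicate: str
    n_genes_used: int
    slope: float
    intercept: float
    r_squared: float
    p_slope_zero: float
    p_slope_one: float


@dataclass
class SlopeSummary:
    fits: list[SlopeFit]
    mean_slope: float
    ci95: tuple[float, float]
    p_vs_one: float
    n_replicates: int
    flagged: bool = False
    flag_reason: str = ""


# ---------------------------------------------------------------------------


def compute_log_ratios(
    young: pd.Series, old: pd.Series, pseudocount: float = 0.5
) -> pd.Series:
    """Per-gene log2(old/young) after fraction-normalizing each sample.

    Inputs are raw count columns over the same gene universe; the
    pseudocount keeps every ratio finite.
    """
    if not young.index.equals(old.index):
        raise SlopeError("young/old gene universes differ")
    fy = (young.astype(float) + pseudocount)
    fy = fy / fy.sum()
    fo = (old.astype(float) + pseudocount)
    fo = fo / fo.sum()
    return np.log2(fo / fy)


def filter_genes(
    counts: CountMatrix,
    condition_of_sample: Mapping[str, str],
    params: SlopeParams | None = None,
) -> list[str]:
    """Genes retained for the regression.

    Depth rule first: a gene is kept when its raw count reaches
    ``min_depth`` in at least one library of either condition.  Then the
    top-``top_expr_fraction`` most highly expressed genes of each library
    (ties broken by gene order) are pooled and removed.
    """
    params = params or SlopeParams()
    params.validate()
    df = counts.counts
    unknown = [s for s in df.columns if s not in condition_of_sample]
    if unknown:
        raise SlopeError(f"samples without a condition label: {unknown[:5]}")
    keep = (df >= params.min_depth).any(axis=1)
    retained = df.loc[keep]
    if retained.empty:
        raise SlopeError("depth filter removed all genes")
    n_top = int(round(params.top_expr_fraction * retained.shape[0]))
    drop: set[str] = set()
    for s in retained.columns:
        order = retained[s].to_numpy()
        # stable sort: ties resolved by gene order, descending count
        idx = np.argsort(-order, kind="stable")[:n_top]
        drop.update(retained.index[idx])
    result = [g for g in retained.index if g not in drop]
    if not result:
        raise SlopeError("filters removed all genes")
    return result


def top_expressed(counts: pd.Series, fraction: float) -> set[str]:
    """The most highly expressed ``fraction`` of genes in one library."""
    n_top = int(round(fraction * counts.shape[0]))
    idx = np.argsort(-counts.to_numpy(), kind="stable")[:n_top]
    return set(counts.index[idx])


# ---------------------------------------------------------------------------


def _ols(x: np.ndarray, y: np.ndarray, replicate: str) -> SlopeFit:
    if x.shape[0] <= 2:
        raise SlopeError("need more than 2 genes for a regression")
    if np.var(x) == 0:
        raise SlopeError("zero variance in control ratios")
    res = stats.linregress(x, y)
    df = x.shape[0] - 2
    if res.stderr == 0:  # perfect fit
        p_one = 1.0 if res.slope == 1.0 else 0.0
    else:
        t_one = (res.slope - 1.0) / res.stderr
        p_one = 2.0 * stats.t.sf(abs(t_one), df)
    return SlopeFit(
        replicate=replicate,
        n_genes_used=int(x.shape[0]),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope_zero=float(res.pvalue),
        p_slope_one=float(p_one),
    )


def fit_attenuation(
    control_ratios: pd.Series | np.ndarray,
    treated_ratios: pd.Series | np.ndarray,
    replicate: str = "1",
) -> SlopeFit:
    """OLS of treated on control aging ratios (with intercept)."""
    x = np.asarray(control_ratios, dtype=float)
    y = np.asarray(treated_ratios, dtype=float)
    if x.shape != y.shape:
        raise SlopeError("paired ratio vectors differ in length")
    return _ols(x, y, replicate)


def summarize_replicates(fits: Sequence[SlopeFit]) -> SlopeSummary:
    """Replicate-averaged slope with t-based CI and test against 1."""
    if len(fits) < 2:
        raise SlopeError("need >= 2 replicate fits to summarize")
    slopes = np.array([f.slope for f in fits])
    n = slopes.shape[0]
    mean = float(slopes.mean())
    sd = float(slopes.std(ddof=1))
    if sd == 0:
        warnings.warn("degenerate variance: all replicate slopes identical",
                      stacklevel=2)
        return SlopeSummary(
            fits=list(fits),
            mean_slope=mean,
            ci95=(mean, mean),
            p_vs_one=1.0 if mean == 1.0 else 0.0,
            n_replicates=n,
            flagged=True,
            flag_reason="degenerate variance",
        )
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    t_stat = (mean - 1.0) / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t_stat), n - 1))
    return SlopeSummary(
        fits=list(fits),
        mean_slope=mean,
        ci95=(mean - half, mean + half),
        p_vs_one=p,
        n_replicates=n,
    )


# ---------------------------------------------------------------------------
# replicate-paired pipeline
# ---------------------------------------------------------------------------


def replicate_ratios(
    counts: CountMatrix,
    design: SampleDesign,
    young: str,
    old: str,
    condition: str,
    genes: Sequence[str],
    params: SlopeParams | None = None,
) -> dict[int, pd.Series]:
    """Old/young log2 ratios per replicate for one condition, restricted to
    ``genes``."""
    params = params or SlopeParams()
    table = design.table
    reps = sorted(
        set(
            table[(table["condition"] == condition)]["replicate"].astype(int)
        )
    )
    out: dict[int, pd.Series] = {}
    for rep in reps:
        sel = table[
            (table["condition"] == condition)
            & (table["replicate"].astype(int) == rep)
        ]
        young_ids = sel.index[sel["stage_or_timepoint"] == young]
        old_ids = sel.index[sel["stage_or_timepoint"] == old]
        if len(young_ids) != 1 or len(old_ids) != 1:
            raise SlopeError(
                f"replicate {rep} of {condition!r} does not have exactly one "
                f"{young!r} and one {old!r} sample"
            )
        ratios = compute_log_ratios(
            counts.counts[young_ids[0]],
            counts.counts[old_ids[0]],
            params.pseudocount_reads,
        )
        out[rep] = ratios.loc[list(genes)]
    return out


def attenuation_analysis(
    counts: CountMatrix,
    design: SampleDesign,
    young: str = "young",
    old: str = "old",
    control: str = "control",
    treated: str = "overexpressor",
    params: SlopeParams | None = None,
    tissues: Mapping[str, Sequence[str]] | None = None,
) -> tuple[SlopeSummary, dict[str, SlopeSummary]]:
    """Full attenuation analysis on a young/old, control/test count matrix.

    Replicates are paired control<->treated by replicate index.  Returns the
    transcriptome-wide summary and, if tissue gene lists are given, one
    summary per tissue (tissues with < 20 usable genes are flagged and not
    fitted).
    """
    params = params or SlopeParams()
    params.validate()
    cond = {
        s: str(design.table.at[s, "condition"]) for s in counts.samples
    }
    genes = filter_genes(counts, cond, params)
    control_ratios = replicate_ratios(
        counts, design, young, old, control, genes, params
    )
    treated_ratios = replicate_ratios(
        counts, design, young, old, treated, genes, params
    )
    if set(control_ratios) != set(treated_ratios):
        raise SlopeError("control and treated replicate indices differ")

    fits = [
        fit_attenuation(control_ratios[rep], treated_ratios[rep], str(rep))
        for rep in sorted(control_ratios)
    ]
    overall = summarize_replicates(fits)

    per_tissue: dict[str, SlopeSummary] = {}
    if tissues:
        gene_set = set(genes)
        for tissue, members in tissues.items():
            usable = [g for g in members if g in gene_set]
            if len(usable) < 20:
                per_tissue[tissue] = SlopeSummary(
                    fits=[],
                    mean_slope=float("nan"),
                    ci95=(float("nan"), float("nan")),
                    p_vs_one=float("nan"),
                    n_replicates=0,
                    flagged=True,
                    flag_reason=f"only {len(usable)} usable genes",
                )
                continue
            t_fits = [
                fit_attenuation(
                    control_ratios[rep].loc[usable],
                    treated_ratios[rep].loc[usable],
                    str(rep),
                )
                for rep in sorted(control_ratios)
            ]
            per_tissue[tissue] = summarize_replicates(t_fits)
    return overall, per_tissue


def tissue_slopes(
    control_ratios: Mapping[int, pd.Series],
    treated_ratios: Mapping[int, pd.Series],
    tissues: Mapping[str, Sequence[str]],
    params: SlopeParams | None = None,
) -> dict[str, SlopeSummary]:
    """Per-tissue replicate-averaged slopes from precomputed ratio vectors."""
    out: dict[str, SlopeSummary] = {}
    for tissue, members in tissues.items():
        usable = [
            g
            for g in members
            if all(g in control_ratios[r].index for r in control_ratios)
        ]
        if len(usable) < 20:
            out[tissue] = SlopeSummary(
                fits=[],
                mean_slope=float("nan"),
                ci95=(float("nan"), float("nan")),
                p_vs_one=float("nan"),
                n_replicates=0,
                flagged=True,
                flag_reason=f"only {len(usable)} usable genes",
            )
            continue
        fits = [
            fit_attenuation(
                control_ratios[rep].loc[usable],
                treated_ratios[rep].loc[usable],
                str(rep),
            )
            for rep in sorted(control_ratios)
        ]
        out[tissue] = summarize_replicates(fits)
    return out


def compare_conditions(
    ratios_a: pd.Series | np.ndarray,
    ratios_b: pd.Series | np.ndarray,
) -> tuple[float, float]:
    """Cross-condition scatter summary: (slope, R^2) of B regressed on A.

    Used to compare two aging programs on a shared gene universe; an
    unrelated program gives R^2 near 0.
    """
    fit = fit_attenuation(ratios_a, ratios_b, replicate="cross")
    return fit.slope, fit.r_squared
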