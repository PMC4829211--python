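"""Timecourse utilities: baseline normalization, direction summaries,
cross-experiment sign concordance, and K-S comparisons.

A trajectory matrix holds per-gene log2 ratios to the first timepoint, so
its first column is identically zero.  Sign concordance between two change
vectors is summarized as a percentage with a one-sided exact binomial test
against a null of 0.5; distribution shifts between gene sets use the
two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gene_classes import round_half_away


class TrajectoryError(ValueError):
    pass


@dataclass
class ConcordanceResult:
    n_pairs: int
    n_concordant: int
    n_excluded_zero: int
    percent: int
    binomial_p_onesided: float


def normalize_to_baseline(
    expr: pd.DataFrame,
    scale: str = "linear",
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Log2 ratios to the first timepoint; replicate columns averaged first.

    ``expr`` is genes x timepoints; duplicate column labels are replicate
    measurements of one timepoint and are averaged (on the given scale)
    before ratio formation.  ``scale="linear"`` divides by the baseline and
    takes log2; ``scale="log2-input"`` subtracts the baseline column.
    """
    if scale not in ("linear", "log2-input"):
        raise TrajectoryError(f"unknown scale {scale!r}")
    # average replicate timepoints, preserving first-seen column order
    order = list(dict.fromkeys(expr.columns))
    mat = expr.T.groupby(level=0, sort=False).mean().T[order]
    if scale == "log2-input":
        return mat.sub(mat.iloc[:, 0], axis=0)
    mat = mat.astype(float) + pseudocount
    if (mat.iloc[:, 0] <= 0).any():
        raise TrajectoryError(
            "non-positive baseline expression; supply a pseudocount"
        )
    return np.log2(mat.div(mat.iloc[:, 0], axis=0))


def direction_summary(
    traj: pd.DataFrame, gene_set: set[str] | None = None
) -> dict[str, float]:
    """Fractions of genes increasing / decreasing / flat between the first
    and last timepoint of a trajectory matrix."""
    if gene_set is not None:
        missing = gene_set - set(traj.index)
        if missing:
            raise TrajectoryError(
                f"gene set members absent from trajectory: "
                f"{sorted(missing)[:5]}"
            )
        traj = traj.loc[sorted(gene_set)]
    final = traj.iloc[:, -1].to_numpy()
    n = final.shape[0]
    if n == 0:
        raise TrajectoryError("empty gene set")
    return {
        "increasing": float((final > 0).sum() / n),
        "decreasing": float((final < 0).sum() / n),
        "flat": float((final == 0).sum() / n),
    }


def sign_concordance(
    changes_a: pd.Series, changes_b: pd.Series
) -> ConcordanceResult:
    """Sign concordance of two per-gene change vectors on a shared universe.

    Genes with a zero change in either vector are excluded (and counted
    separately), not treated as discordant.  The p-value is the one-sided
    exact binomial tail P(X >= n_concordant | n_pairs, 0.5).
    """
    shared = changes_a.index.intersection(changes_b.index)
    a = changes_a.loc[shared].to_numpy(dtype=float)
    b = changes_b.loc[shared].to_numpy(dtype=float)
    nonzero = (a != 0) & (b != 0)
    n_excluded = int((~nonzero).sum())
    a, b = a[nonzero], b[nonzero]
    n_pairs = int(a.shape[0])
    if n_pairs == 0:
        raise TrajectoryError("no usable gene pairs after exclusions")
    n_conc = int((np.sign(a) == np.sign(b)).sum())
    p = float(stats.binom.sf(n_conc - 1, n_pairs, 0.5))
    return ConcordanceResult(
        n_pairs=n_pairs,
        n_concordant=n_conc,
        n_excluded_zero=n_excluded,
        percent=round_half_away(100.0 * n_conc / n_pairs),
        binomial_p_onesided=p,
    )


def concordance_from_counts(n_concordant: int, n_pairs: int) -> ConcordanceResult:
    """Concordance summary from already-tallied counts."""
    if n_concordant > n_pairs or n_pairs <= 0:
        raise TrajectoryError("invalid concordance counts")
    p = float(stats.binom.sf(n_concordant - 1, n_pairs, 0.5))
    return ConcordanceResult(
        n_pairs=n_pairs,
        n_concordant=n_concordant,
        n_excluded_zero=0,
        percent=round_half_away(100.0 * n_concordant / n_pairs),
        binomial_p_onesided=p,
    )


def ks_compare(
    values_a: pd.Series | np.ndarray, values_b: pd.Series | np.ndarray
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test (asymptotic p).

    D is the maximum gap between the two empirical CDFs.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise TrajectoryError("both samples must have size >= 2")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
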