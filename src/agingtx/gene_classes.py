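"""Cross-stage classification of regulated genes.

Genes called differentially expressed after knockdown at the L1 or L4
larval stage are partitioned by sign-and-significance concordance with the
other stage:

* general   — in a stage's DE list and the other stage shows a change of
              the same sign with p below ``p_conc`` (default 0.05);
* establishment — L1-called only, not concordant-and-significant at L4;
* adult     — L4-called only, not concordant-and-significant at L1;
* discordant — called at both stages with opposite signs;
* unclassified — missing from one stage's measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASSES = ("general", "establishment", "adult", "discordant", "unclassified")


class ClassifyError(ValueError):
    pass


@dataclass
class ClassAssignment:
    table: pd.DataFrame  # index gene_id, column "gene_class"

    def genes_in(self, gene_class: str) -> set[str]:
        t = self.table
        return set(t.index[t["gene_class"] == gene_class])


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def classify_genes(
    stats_l1: pd.DataFrame,
    stats_l4: pd.DataFrame,
    p_conc: float = 0.05,
) -> ClassAssignment:
    """Assign each gene in the union of the two DE lists to a class.

    Both inputs are indexed by gene id with columns ``log2_fc``, ``p`` and
    ``in_de_list`` (see :func:`agingtx.rankprod_de.stage_stats`).  Genes
    absent from one stage's table are unclassified.
    """
    if not (0 < p_conc < 1):
        raise ClassifyError("p_conc must be in (0, 1)")
    l1_list = set(stats_l1.index[stats_l1["in_de_list"]])
    l4_list = set(stats_l4.index[stats_l4["in_de_list"]])
    rows = {}
    for gene in sorted(l1_list | l4_list):
        in_l1 = gene in stats_l1.index
        in_l4 = gene in stats_l4.index
        if not (in_l1 and in_l4):
            rows[gene] = "unclassified"
            continue
        fc1 = float(stats_l1.at[gene, "log2_fc"])
        fc4 = float(stats_l4.at[gene, "log2_fc"])
        p1 = float(stats_l1.at[gene, "p"])
        p4 = float(stats_l4.at[gene, "p"])
        concordant = _sign(fc1) == _sign(fc4) and _sign(fc1) != 0
        if gene in l1_list and gene in l4_list and not concordant:
            rows[gene] = "discordant"
        elif gene in l1_list:
            rows[gene] = (
                "general" if concordant and p4 < p_conc else "establishment"
            )
        else:  # L4 list only
            rows[gene] = "general" if concordant and p1 < p_conc else "adult"
    table = pd.DataFrame(
        {"gene_class": pd.Series(rows, dtype=object)}
    )
    table.index.name = "gene_id"
    return ClassAssignment(table)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(np.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def class_summary(assignment: ClassAssignment) -> pd.DataFrame:
    """Counts and integer percentages per class.

    Percentages are over classified genes (the three named classes;
    discordant and unclassified excluded) and rounded half away from zero.
    """
    counts = {c: len(assignment.genes_in(c)) for c in CLASSES}
    total = counts["general"] + counts["establishment"] + counts["adult"]
    rows = []
    for c in CLASSES:
        if c in ("general", "establishment", "adult") and total > 0:
            pct = round_half_away(100.0 * counts[c] / total)
        else:
            pct = 0
        rows.append((c, counts[c], pct))
    return pd.DataFrame(rows, columns=["gene_class", "count", "percent"])


def summary_percentages(counts: dict[str, int]) -> dict[str, int]:
    """Integer percentages from raw class counts (same rounding rule)."""
    total = sum(counts.values())
    if total == 0:
        return {c: 0 for c in counts}
    return {c: round_half_away(100.0 * n / total) for c, n in counts.items()}
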