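"""Synthetic datasets with planted ground truth for every pipeline stage.

The generator emulates, at desk scale, the four kinds of input the pipeline
consumes:

* a tiled gene annotation on a handful of chromosomes,
* a panel of ChIP-seq peak datasets (two jittered replicates each) with
  promiscuously-bound "hot" sites and factor-specific sites, one factor's
  specific targets planted to overlap an age-regulated gene set at a chosen
  enrichment fold,
* RNAi-vs-control count matrices at two larval stages with planted down- and
  up-regulated genes in three cross-stage concordance classes, and
* young/old aging timecourses in a control and an overexpressor condition
  where the overexpressor's true per-gene aging effect is the control effect
  multiplied by a per-tissue attenuation factor alpha.

Counts are drawn from a negative binomial (gamma-Poisson) with log-normal
gene-wise means, the standard overdispersed-count model for bulk RNA-seq.
Every ``simulate_*`` call derives its RNG stream from ``config.seed`` plus a
call-specific offset, so adding one stage never perturbs another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    CountMatrix,
    GeneModel,
    GeneSet,
    Peak,
    PeakSet,
    SampleDesign,
    provenance_header,
)

# stable per-stage RNG offsets (annotation is deterministic, no stream)
_OFFSET_CHIP = 1
_OFFSET_COUNTS = 2
_OFFSET_TIMECOURSE = 3
_OFFSET_TRAJECTORY = 4

DE_CLASSES = ("both", "l1_only", "l4_only")


class SimulationError(ValueError):
    """Invalid or unsatisfiable simulation configuration."""


@dataclass
class SimulationConfig:
    """All knobs for the synthetic study, with desk-scale defaults.

    The defaults mirror the shape of the study the pipeline was built for:
    99 ChIP-seq datasets over 58 factors with hot sites broader than the
    complexity threshold; an age-regulated set enriched ~2.1-fold among the
    planted factor's targets; 3-replicate RNAi-vs-control counts at two
    stages; and 5-replicate young/old timecourses in which the
    overexpressor's aging effects are damped per tissue (alpha ~ 0.85-1.0,
    germline unaffected).  Noise magnitudes are the package's own choices
    (none are published) and are documented in docs/methods.md.
    """

    # annotation
    n_genes: int = 2000
    n_chroms: int = 6
    gene_length_bp: int = 2000
    intergenic_bp: int = 8000
    noise_margin_bp: int = 60000  # reserved per-chromosome tail for
    # replicate-private noise peaks

    # ChIP panel
    n_factors: int = 58
    n_datasets: int = 99
    hot_site_count: int = 60
    hot_site_breadth: int = 12  # factors per hot site
    specific_peaks_per_factor: int = 250
    peak_halfwidth_bp: int = 75
    replicate_jitter_bp: int = 25
    noise_peak_fraction: float = 0.10
    planted_factor: str = "TF00"
    age_set_size: int = 200
    planted_enrichment_fold: float = 2.1

    # count model
    nb_dispersion: float = 0.05
    mean_log_expression: float = 5.0  # natural-log scale of gene means
    sd_log_expression: float = 1.5
    library_size: int = 400_000
    library_size_jitter: float = 0.20

    # planted differential expression (counts per class, by direction)
    planted_down: dict[str, int] = field(
        default_factory=lambda: {"both": 50, "l1_only": 25, "l4_only": 25}
    )
    planted_up: dict[str, int] = field(
        default_factory=lambda: {"both": 10, "l1_only": 5, "l4_only": 5}
    )
    lfc_magnitude: float = 2.0
    n_replicates_de: int = 3

    # aging timecourse
    n_timepoints: int = 2  # young / old
    n_replicates_timecourse: int = 5
    attenuation_by_tissue: dict[str, float] = field(
        default_factory=lambda: {
            "intestine": 0.85,
            "muscle": 0.90,
            "hypodermis": 0.90,
            "neurons": 0.90,
            "germline": 1.0,
            "other": 0.87,
        }
    )
    genes_per_tissue: int = 200
    trajectory_sd: float = 1.2  # sd of true aging effects (log2)
    strong_fraction: float = 0.15  # strongly age-regulated subset
    strong_sd: float = 2.5
    ratio_noise_sd: float = 0.05  # per-replicate log2 noise on aging effect
    replicate_attenuation_sd: float = 0.03  # cohort-level alpha variability
    timecourse_nb_dispersion: float = 0.0005
    timecourse_library_size: int = 40_000_000
    timecourse_sd_log_expression: float = 1.0

    seed: int = 0

    def validate(self) -> None:
        positive = [
            "n_genes", "n_chroms", "gene_length_bp", "intergenic_bp",
            "n_factors", "n_datasets", "hot_site_count", "hot_site_breadth",
            "specific_peaks_per_factor", "age_set_size", "n_timepoints",
            "n_replicates_de", "n_replicates_timecourse", "library_size",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.planted_enrichment_fold < 1:
            raise SimulationError("planted_enrichment_fold must be >= 1")
        for tissue, alpha in self.attenuation_by_tissue.items():
            if not (0 < alpha <= 1.5):
                raise SimulationError(
                    f"attenuation for tissue {tissue!r} must be in (0, 1.5]"
                )
        if self.n_datasets < self.n_factors:
            raise SimulationError("n_datasets must be >= n_factors")
        for d in (self.planted_down, self.planted_up):
            for cls in d:
                if cls not in DE_CLASSES:
                    raise SimulationError(f"unknown DE class {cls!r}")


def l1_experiment_config(**overrides) -> SimulationConfig:
    """Preset shaped like the stage-L1 RNAi experiment: 153 genes planted
    down and 9 up at L1 only.

    Direct-target effects of a near-complete knockdown are strong (here
    2**2.5 ~ 5.7-fold) and deep 3'-tag libraries from pooled synchronized
    populations are tight (NB dispersion 0.02).
    """
    cfg = SimulationConfig(
        planted_down={"both": 0, "l1_only": 153, "l4_only": 0},
        planted_up={"both": 0, "l1_only": 9, "l4_only": 0},
        lfc_magnitude=2.5,
        nb_dispersion=0.02,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class PlantedTruth:
    """Ground truth serialized alongside every simulated dataset."""

    # DE: gene -> (direction, class); keyed per planted gene
    de_direction: dict[str, str] = field(default_factory=dict)
    de_class: dict[str, str] = field(default_factory=dict)
    age_set: frozenset[str] = frozenset()
    planted_factor: str = ""
    planted_targets: frozenset[str] = frozenset()
    tissue_of_gene: dict[str, str] = field(default_factory=dict)
    attenuation_by_tissue: dict[str, float] = field(default_factory=dict)
    replicate_attenuation_shift: list[float] = field(default_factory=list)
    true_aging_effect: dict[str, float] = field(default_factory=dict)

    def de_genes(self, direction: str | None = None) -> set[str]:
        if direction is None:
            return set(self.de_direction)
        return {g for g, d in self.de_direction.items() if d == direction}

    def write(self, path: str | Path) -> None:
        """Flat TSV (gene rows) with a key-value comment header."""
        path = Path(path)
        genes = sorted(
            set(self.de_direction)
            | self.age_set
            | self.planted_targets
            | set(self.tissue_of_gene)
            | set(self.true_aging_effect)
        )
        with open(path, "w") as fh:
            fh.write(provenance_header(kind="planted_truth") + "\n")
            fh.write(f"#planted_factor={self.planted_factor}\n")
            for tissue, alpha in sorted(self.attenuation_by_tissue.items()):
                fh.write(f"#alpha_{tissue}={alpha!r}\n")
            for i, shift in enumerate(self.replicate_attenuation_shift):
                fh.write(f"#replicate_alpha_shift_{i}={shift!r}\n")
            fh.write(
                "gene_id\tde_direction\tde_class\tin_age_set\t"
                "is_planted_target\ttissue\ttrue_aging_effect\n"
            )
            for g in genes:
                fh.write(
                    "\t".join(
                        [
                            g,
                            self.de_direction.get(g, "."),
                            self.de_class.get(g, "."),
                            "1" if g in self.age_set else "0",
                            "1" if g in self.planted_targets else "0",
                            self.tissue_of_gene.get(g, "."),
                            repr(self.true_aging_effect[g])
                            if g in self.true_aging_effect
                            else ".",
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def read(cls, path: str | Path) -> "PlantedTruth":
        truth = cls()
        alpha: dict[str, float] = {}
        shifts: dict[int, float] = {}
        with open(path) as fh:
            header: list[str] | None = None
            for raw in fh:
                line = raw.rstrip("\n")
                if line.startswith("#planted_factor="):
                    truth.planted_factor = line.split("=", 1)[1]
                    continue
                if line.startswith("#alpha_"):
                    key, val = line[len("#alpha_"):].split("=", 1)
                    alpha[key] = float(val)
                    continue
                if line.startswith("#replicate_alpha_shift_"):
                    key, val = line[len("#replicate_alpha_shift_"):].split("=", 1)
                    shifts[int(key)] = float(val)
                    continue
                if line.startswith("#"):
                    continue
                fields = line.split("\t")
                if header is None:
                    header = fields
                    continue
                row = dict(zip(header, fields))
                g = row["gene_id"]
                if row["de_direction"] != ".":
                    truth.de_direction[g] = row["de_direction"]
                if row["de_class"] != ".":
                    truth.de_class[g] = row["de_class"]
                if row["in_age_set"] == "1":
                    truth.age_set |= {g}
                if row["is_planted_target"] == "1":
                    truth.planted_targets |= {g}
                if row["tissue"] != ".":
                    truth.tissue_of_gene[g] = row["tissue"]
                if row["true_aging_effect"] != ".":
                    truth.true_aging_effect[g] = float(row["true_aging_effect"])
        truth.attenuation_by_tissue = alpha
        truth.replicate_attenuation_shift = [
            shifts[i] for i in sorted(shifts)
        ]
        return truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Tile genes on chromosomes with fixed lengths and gaps.

    Genes alternate strand; TSS spacing is ``gene_length_bp +
    intergenic_bp``.  A noise margin is reserved at each chromosome end for
    replicate-private peaks.  Deterministic (no RNG draws).
    """
    config.validate()
    n_per_chrom = math.ceil(config.n_genes / config.n_chroms)
    pitch = config.gene_length_bp + config.intergenic_bp
    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    gene_idx = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n_here = min(n_per_chrom, config.n_genes - gene_idx)
        for i in range(n_here):
            start = config.intergenic_bp + i * pitch
            strand = "+" if i % 2 == 0 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"g{gene_idx:05d}",
                    chrom=chrom,
                    start=start,
                    end=start + config.gene_length_bp,
                    strand=strand,
                )
            )
            gene_idx += 1
        chrom_sizes[chrom] = (
            config.intergenic_bp + n_here * pitch + config.noise_margin_bp
        )
    if gene_idx != config.n_genes:
        raise SimulationError("genes do not fit on chromosomes")
    return genes, chrom_sizes


# ---------------------------------------------------------------------------
# ChIP panel
# ---------------------------------------------------------------------------


def _dataset_plan(config: SimulationConfig) -> list[tuple[str, str]]:
    """(factor, stage) pairs: every factor has an L1 dataset; the first
    ``n_datasets - n_factors`` factors are additionally profiled at L4."""
    factors = [f"TF{i:02d}" for i in range(config.n_factors)]
    plan = [(f, "L1") for f in factors]
    extra = config.n_datasets - config.n_factors
    if extra > len(factors):
        raise SimulationError(
            "n_datasets exceeds two stages per factor; reduce n_datasets"
        )
    plan += [(factors[i], "L4") for i in range(extra)]
    return plan


def _place_peak(
    gene: GeneModel, rng: np.random.Generator, config: SimulationConfig
) -> int:
    """Summit uniform in the near-upstream 2.5 kb of the TSS (strand-aware).

    Near-upstream placement keeps each planted summit inside exactly one
    gene's assignment region given the default intergenic spacing, so the
    planted target list is exact.
    """
    margin = min(2500, config.intergenic_bp // 3)
    if gene.strand == "+":
        return int(rng.integers(gene.tss - margin, gene.tss))
    return int(rng.integers(gene.tss, gene.tss + margin))


def _jittered(
    chrom: str,
    summit: int,
    score: float,
    rng: np.random.Generator,
    config: SimulationConfig,
    chrom_sizes: Mapping[str, int],
) -> Peak:
    shift = int(rng.integers(-config.replicate_jitter_bp,
                             config.replicate_jitter_bp + 1))
    s = summit + shift
    start = max(0, s - config.peak_halfwidth_bp)
    end = min(chrom_sizes[chrom], s + config.peak_halfwidth_bp)
    return Peak(chrom, start, end, s, score)


def simulate_chip_datasets(
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[list[tuple[PeakSet, PeakSet]], GeneSet, PlantedTruth]:
    """Simulate the ChIP-seq panel with a planted enriched factor.

    Returns one (replicate 1, replicate 2) pair per dataset, the
    age-regulated gene set, and the planted truth.  Hot sites receive peaks
    from ``hot_site_breadth`` factors so they fail any complexity filter
    with a threshold below that breadth; each factor's specific peaks sit in
    the near-upstream window of its target genes; the planted factor's
    targets overlap the age set at ``planted_enrichment_fold`` times the
    hypergeometric expectation.  Each true peak appears in both replicates
    with +/- jitter; replicate-private noise peaks are placed on disjoint
    lattices in the reserved chromosome margin so they can never survive
    replicate intersection.
    """
    config.validate()
    if chrom_sizes is None:
        _, chrom_sizes = simulate_annotation(config)
    rng = np.random.default_rng(config.seed + _OFFSET_CHIP)
    gene_ids = [g.gene_id for g in genes]
    by_id = {g.gene_id: g for g in genes}
    universe = len(gene_ids)

    age_members = rng.choice(gene_ids, size=config.age_set_size, replace=False)
    age_set = GeneSet("age_regulated", frozenset(map(str, age_members)))

    n_targets = config.specific_peaks_per_factor
    expected = n_targets * config.age_set_size / universe
    planted_overlap = int(round(config.planted_enrichment_fold * expected))
    if planted_overlap > min(n_targets, config.age_set_size):
        max_fold = min(n_targets, config.age_set_size) / expected
        raise SimulationError(
            "requested enrichment impossible: maximum achievable fold is "
            f"{max_fold:.2f}"
        )

    plan = _dataset_plan(config)
    if config.planted_factor not in {f for f, _ in plan}:
        raise SimulationError(
            f"planted_factor {config.planted_factor!r} not in the panel"
        )

    # hot sites: near-upstream of random genes, shared by many L1 factors
    l1_factors = sorted({f for f, s in plan if s == "L1"})
    if config.hot_site_breadth > len(l1_factors):
        raise SimulationError("hot_site_breadth exceeds number of L1 factors")
    hot_genes = rng.choice(gene_ids, size=config.hot_site_count, replace=False)
    hot_sites = []  # (chrom, summit, member factors)
    for hg in hot_genes:
        g = by_id[str(hg)]
        summit = _place_peak(g, rng, config)
        members = rng.choice(l1_factors, size=config.hot_site_breadth,
                             replace=False)
        hot_sites.append((g.chrom, summit, set(map(str, members))))

    age_list = sorted(age_set.members)
    non_age = sorted(set(gene_ids) - age_set.members)

    datasets: list[tuple[PeakSet, PeakSet]] = []
    planted_targets: frozenset[str] = frozenset()
    for factor, stage in plan:
        if factor == config.planted_factor and stage == "L1":
            inside = rng.choice(age_list, size=planted_overlap, replace=False)
            outside = rng.choice(
                non_age, size=n_targets - planted_overlap, replace=False
            )
            targets = [str(t) for t in inside] + [str(t) for t in outside]
            planted_targets = frozenset(targets)
        else:
            targets = [
                str(t)
                for t in rng.choice(gene_ids, size=n_targets, replace=False)
            ]
        true_peaks: list[tuple[str, int, float]] = []
        for t in targets:
            g = by_id[t]
            true_peaks.append(
                (g.chrom, _place_peak(g, rng, config), float(rng.uniform(1, 100)))
            )
        if stage == "L1":
            for chrom, summit, members in hot_sites:
                if factor in members:
                    true_peaks.append((chrom, summit, float(rng.uniform(1, 100))))

        reps: list[PeakSet] = []
        n_noise = int(round(config.noise_peak_fraction * len(true_peaks)))
        chroms = sorted(chrom_sizes)
        for rep in (1, 2):
            peaks = [
                _jittered(chrom, summit, score, rng, config, chrom_sizes)
                for chrom, summit, score in true_peaks
            ]
            # replicate-private noise on a per-replicate lattice in the margin
            for j in range(n_noise):
                chrom = chroms[int(rng.integers(len(chroms)))]
                margin_start = chrom_sizes[chrom] - config.noise_margin_bp
                slot = 2 * j + (rep - 1)
                start = margin_start + slot * 400
                end = start + 150
                if end > chrom_sizes[chrom]:
                    continue
                peaks.append(Peak(chrom, start, end, (start + end) // 2,
                                  float(rng.uniform(1, 100))))
            reps.append(PeakSet(factor, stage, rep, peaks).sorted())
        datasets.append((reps[0], reps[1]))

    truth = PlantedTruth(
        age_set=age_set.members,
        planted_factor=config.planted_factor,
        planted_targets=planted_targets,
    )
    return datasets, age_set, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2 (Poisson when
    dispersion == 0)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def make_de_design(config: SimulationConfig) -> SampleDesign:
    """Two conditions x two stages x n replicates."""
    rows = []
    for stage in ("L1", "L4"):
        for condition in ("control", "treated"):
            for rep in range(1, config.n_replicates_de + 1):
                sid = f"{condition}_{stage}_r{rep}"
                rows.append((sid, condition, stage, rep))
    df = pd.DataFrame(
        rows, columns=["sample_id", "condition", "stage_or_timepoint",
                       "replicate"]
    ).set_index("sample_id")
    return SampleDesign(df)


def simulate_counts(
    genes: Sequence[GeneModel],
    design: SampleDesign,
    config: SimulationConfig,
) -> tuple[CountMatrix, PlantedTruth]:
    """RNAi-vs-control counts with planted DE genes in three classes.

    Planted genes have their treated-condition mean multiplied by
    ``2**(+/- lfc_magnitude)`` at the stage(s) their class dictates: the
    "both" class at both stages with the same sign, "l1_only"/"l4_only" at
    one stage.  Library sizes vary by ``+/- library_size_jitter``.
    """
    config.validate()
    conditions = design.table["condition"].unique()
    for cond in conditions:
        for stage in design.table["stage_or_timepoint"].unique():
            n = len(design.select(cond, stage))
            if n < 2:
                raise SimulationError(
                    f"fewer than 2 replicates for {cond}/{stage}"
                )
    rng = np.random.default_rng(config.seed + _OFFSET_COUNTS)
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)

    base_mean = rng.lognormal(
        config.mean_log_expression, config.sd_log_expression, size=n
    )

    n_planted = sum(config.planted_down.values()) + sum(
        config.planted_up.values()
    )
    if n_planted > n:
        raise SimulationError("more planted DE genes than genes")
    planted_idx = rng.choice(n, size=n_planted, replace=False)
    truth = PlantedTruth()
    cursor = 0
    # per-gene multiplicative effect on the treated mean, by stage
    effect = {"L1": np.ones(n), "L4": np.ones(n)}
    for direction, table in (("down", config.planted_down),
                             ("up", config.planted_up)):
        sign = -1.0 if direction == "down" else 1.0
        for cls in DE_CLASSES:
            for _ in range(table.get(cls, 0)):
                gi = int(planted_idx[cursor])
                cursor += 1
                gid = gene_ids[gi]
                truth.de_direction[gid] = direction
                truth.de_class[gid] = cls
                mult = 2.0 ** (sign * config.lfc_magnitude)
                if cls in ("both", "l1_only"):
                    effect["L1"][gi] = mult
                if cls in ("both", "l4_only"):
                    effect["L4"][gi] = mult

    cols: dict[str, np.ndarray] = {}
    for sid in design.samples:
        row = design.table.loc[sid]
        mu = base_mean.copy()
        if row["condition"] != "control":
            mu = mu * effect[str(row["stage_or_timepoint"])]
        lib = config.library_size * rng.uniform(
            1 - config.library_size_jitter, 1 + config.library_size_jitter
        )
        mu = mu * (lib / mu.sum())
        cols[sid] = _nb_draw(rng, mu, config.nb_dispersion)
    cm = CountMatrix(pd.DataFrame(cols, index=gene_ids))
    return cm, truth


# ---------------------------------------------------------------------------
# aging timecourse
# ---------------------------------------------------------------------------


def make_timecourse_design(config: SimulationConfig) -> SampleDesign:
    rows = []
    for condition in ("control", "overexpressor"):
        for timepoint in ("young", "old"):
            for rep in range(1, config.n_replicates_timecourse + 1):
                sid = f"{condition}_{timepoint}_r{rep}"
                rows.append((sid, condition, timepoint, rep))
    df = pd.DataFrame(
        rows, columns=["sample_id", "condition", "stage_or_timepoint",
                       "replicate"]
    ).set_index("sample_id")
    return SampleDesign(df)


def simulate_aging_timecourse(
    genes: Sequence[GeneModel],
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleDesign, PlantedTruth]:
    """Young/old counts for control and overexpressor, 5 replicates each.

    Each gene g carries a true control aging effect ``r_g ~ N(0,
    trajectory_sd)`` on the log2 scale (a ``strong_fraction`` subset drawn
    with ``strong_sd`` represents strongly age-regulated genes).  The
    overexpressor's true effect is ``alpha_tissue(g) * r_g``; each replicate
    cohort shifts all its tissue alphas by a common ``N(0,
    replicate_attenuation_sd)`` draw (replicate populations age at slightly
    different rates); observed old-vs-young log-ratios add per-replicate
    Normal noise; counts are back-transformed through the negative-binomial
    model at deep 3'-tag coverage.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + _OFFSET_TIMECOURSE)
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)

    tissues = [t for t in config.attenuation_by_tissue if t != "other"]
    if "other" not in config.attenuation_by_tissue:
        raise SimulationError("attenuation_by_tissue must define 'other'")
    tissue_label = np.full(n, "other", dtype=object)
    need = config.genes_per_tissue * len(tissues)
    if need > n:
        raise SimulationError("genes_per_tissue too large for n_genes")
    chosen = rng.choice(n, size=need, replace=False)
    for k, tissue in enumerate(tissues):
        idx = chosen[k * config.genes_per_tissue:(k + 1) * config.genes_per_tissue]
        tissue_label[idx] = tissue
    alpha_gene = np.array(
        [config.attenuation_by_tissue[t] for t in tissue_label]
    )

    r = rng.normal(0.0, config.trajectory_sd, size=n)
    strong = rng.random(n) < config.strong_fraction
    r[strong] = rng.normal(0.0, config.strong_sd, size=int(strong.sum()))

    base_mean = rng.lognormal(
        config.mean_log_expression, config.timecourse_sd_log_expression, size=n
    )
    rep_shift = rng.normal(
        0.0, config.replicate_attenuation_sd, size=config.n_replicates_timecourse
    )

    design = make_timecourse_design(config)
    cols: dict[str, np.ndarray] = {}
    for sid in design.samples:
        row = design.table.loc[sid]
        rep = int(row["replicate"]) - 1
        if row["stage_or_timepoint"] == "young":
            log2_shift = np.zeros(n)
        else:
            if row["condition"] == "control":
                true_effect = r
            else:
                true_effect = (alpha_gene + rep_shift[rep]) * r
            noise = rng.normal(0.0, config.ratio_noise_sd, size=n)
            log2_shift = true_effect + noise
        mu = base_mean * np.exp2(log2_shift)
        lib = config.timecourse_library_size * rng.uniform(
            1 - config.library_size_jitter, 1 + config.library_size_jitter
        )
        mu = mu * (lib / mu.sum())
        cols[sid] = _nb_draw(rng, mu, config.timecourse_nb_dispersion)

    cm = CountMatrix(pd.DataFrame(cols, index=gene_ids))
    truth = PlantedTruth(
        tissue_of_gene={gene_ids[i]: str(tissue_label[i]) for i in range(n)},
        attenuation_by_tissue=dict(config.attenuation_by_tissue),
        replicate_attenuation_shift=[float(s) for s in rep_shift],
        true_aging_effect={gene_ids[i]: float(r[i]) for i in range(n)},
    )
    return cm, design, truth


# ---------------------------------------------------------------------------
# developmental trajectory matrix (for trajectory utilities)
# ---------------------------------------------------------------------------


def simulate_trajectory_matrix(
    n_genes: int,
    n_timepoints: int = 7,
    frac_increasing: float = 0.93,
    effect_sd: float = 1.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear-scale expression, genes x timepoints, where a chosen fraction
    of genes trends upward from the first to the last timepoint.

    Timepoint labels follow the standard developmental series (EE, LE,
    L1-L4, D1).  Intended for exercising baseline normalization and
    direction summaries.
    """
    rng = np.random.default_rng(seed + _OFFSET_TRAJECTORY)
    labels = ["EE", "LE", "L1", "L2", "L3", "L4", "D1"][:n_timepoints]
    if len(labels) < n_timepoints:
        labels += [f"T{i}" for i in range(len(labels), n_timepoints)]
    slope_sign = np.where(rng.random(n_genes) < frac_increasing, 1.0, -1.0)
    total = slope_sign * np.abs(rng.normal(effect_sd, effect_sd / 4, n_genes))
    t = np.linspace(0.0, 1.0, n_timepoints)
    log2_expr = (
        np.outer(total, t)
        + rng.normal(0.0, noise_sd, size=(n_genes, n_timepoints))
    )
    log2_expr[:, 0] = 0.0  # ratios are relative to the first timepoint
    base = rng.lognormal(3.0, 1.0, size=n_genes)
    expr = base[:, None] * np.exp2(log2_expr)
    return pd.DataFrame(
        expr, index=[f"g{i:05d}" for i in range(n_genes)], columns=labels
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
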