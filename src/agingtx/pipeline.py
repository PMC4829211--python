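"""Configuration-driven orchestration: simulate -> screen -> de ->
classify -> slope -> trajectory, with seeding, logging, and a
machine-readable run report.

A run config is a nested key-value document (YAML).  The single global
seed fans out to per-stage seeds by stable offsets, so any stage can be
re-run in isolation and reproduce its outputs.  Every output TSV carries a
commented provenance header; the JSON report records parameters, input
checksums, row counts and the key statistic of each stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, synthetic_data
from .aging_slope import SlopeParams, attenuation_analysis
from .gene_classes import class_summary, classify_genes
from .genome_io import (
    gene_universe,
    read_count_matrix,
    read_gene_models,
    read_gene_set,
    read_peaks_bed,
    write_count_matrix,
    write_gene_models,
    write_gene_set,
    write_peaks_bed,
)
from .rankprod_de import RankProdParams, rank_product_de, stage_stats
from .regulator_screen import ScreenParams, intersect_replicates, run_screen
from .synthetic_data import SimulationConfig
from .trajectories import direction_summary, normalize_to_baseline

logger = logging.getLogger("agingtx.pipeline")

STAGES = ("simulate", "screen", "de", "classify", "slope", "trajectory")

# per-stage seed offsets (simulation uses the generator's own offsets)
_SEED_OFFSETS = {"de_l1": 11, "de_l4": 12}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "agingtx_run"
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    simulate: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    screen: dict[str, Any] = field(default_factory=dict)
    de: dict[str, Any] = field(default_factory=dict)
    classify: dict[str, Any] = field(default_factory=dict)
    slope: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key == "stages":
                cfg.stages.update(value)
            else:
                setattr(cfg, key, value)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: RunConfig) -> list[str]:
    """All problems that would prevent :func:`run_pipeline` from starting."""
    problems: list[str] = []
    enabled = {s for s in STAGES if config.stages.get(s, False)}
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        problems.append(f"unknown stages: {sorted(unknown)}")
    if not enabled:
        problems.append("no stages enabled")
    if "classify" in enabled and "de" not in enabled:
        problems.append("classify requires the de stage")

    try:
        sim = SimulationConfig(**config.simulate, seed=config.seed)
        sim.validate()
    except (TypeError, ValueError) as exc:
        problems.append(f"simulate: {exc}")

    try:
        sp = ScreenParams(**config.screen)
        sp.validate()
    except (TypeError, ValueError) as exc:
        problems.append(f"screen: {exc}")
    try:
        rp = RankProdParams(**{**config.de, "seed": config.seed})
        rp.validate()
    except (TypeError, ValueError) as exc:
        problems.append(f"de: {exc}")
    p_conc = config.classify.get("p_conc", 0.05)
    if not (0 < p_conc < 1):
        problems.append("classify: p_conc outside (0, 1)")
    try:
        slp = SlopeParams(**config.slope)
        slp.validate()
    except (TypeError, ValueError) as exc:
        problems.append(f"slope: {exc}")

    if not config.stages.get("simulate", False):
        needed = {
            "screen": ["genes", "age_set", "peaks_dir"],
            "de": ["counts", "design"],
            "slope": ["timecourse_counts", "timecourse_design"],
            "trajectory": ["expr"],
        }
        for stage, keys in needed.items():
            if stage not in enabled:
                continue
            for key in keys:
                path = config.inputs.get(key)
                if path is None:
                    problems.append(f"{stage}: missing input {key!r}")
                elif not Path(path).exists():
                    problems.append(f"{stage}: input path not found: {path}")
    return problems


def _write_tsv(df: pd.DataFrame, path: Path, **provenance) -> None:
    from .genome_io import provenance_header

    with open(path, "w") as fh:
        fh.write(provenance_header(**provenance) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; returns the run report.

    Fails fast: pre-flight validation lists every problem at once, and a
    stage failure aborts with the stage named.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("config invalid: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {
        "tool_version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    enabled = {s for s in STAGES if config.stages.get(s, False)}

    sim_cfg = SimulationConfig(**config.simulate, seed=config.seed)
    state: dict[str, Any] = {}

    def record(stage: str, t0: float, **info) -> None:
        report["stages"][stage] = {
            "wall_clock_s": round(time.time() - t0, 3),
            **info,
        }

    # ----- simulate ------------------------------------------------------
    if "simulate" in enabled:
        t0 = time.time()
        logger.info("[simulate] generating synthetic study")
        genes, chrom_sizes = synthetic_data.simulate_annotation(sim_cfg)
        datasets, age_set, chip_truth = synthetic_data.simulate_chip_datasets(
            genes, sim_cfg, chrom_sizes
        )
        design = synthetic_data.make_de_design(sim_cfg)
        counts, de_truth = synthetic_data.simulate_counts(
            genes, design, sim_cfg
        )
        tc_counts, tc_design, tc_truth = (
            synthetic_data.simulate_aging_timecourse(genes, sim_cfg)
        )
        write_gene_models(genes, outdir / "genes.tsv")
        write_gene_set(age_set, outdir / "age_set.tsv")
        peaks_dir = outdir / "peaks"
        peaks_dir.mkdir(exist_ok=True)
        for rep1, rep2 in datasets:
            for rep in (rep1, rep2):
                write_peaks_bed(
                    rep,
                    peaks_dir
                    / f"{rep.factor}.{rep.stage}.rep{rep.replicate}.bed",
                )
        write_count_matrix(
            counts, design, outdir / "counts.tsv", outdir / "design.tsv"
        )
        write_count_matrix(
            tc_counts,
            tc_design,
            outdir / "timecourse_counts.tsv",
            outdir / "timecourse_design.tsv",
        )
        chip_truth.write(outdir / "truth_chip.tsv")
        de_truth.write(outdir / "truth_de.tsv")
        tc_truth.write(outdir / "truth_timecourse.tsv")
        state.update(
            genes=genes,
            age_set=age_set,
            datasets=datasets,
            counts=counts,
            design=design,
            tc_counts=tc_counts,
            tc_design=tc_design,
            tc_truth=tc_truth,
            de_truth=de_truth,
            chip_truth=chip_truth,
        )
        record(
            "simulate",
            t0,
            parameters=synthetic_data.config_to_dict(sim_cfg),
            n_genes=len(genes),
            n_datasets=len(datasets),
        )
    else:
        t0 = time.time()
        if "screen" in enabled:
            state["genes"] = read_gene_models(config.inputs["genes"])
            state["age_set"] = read_gene_set(
                config.inputs["age_set"], "age_regulated"
            )
            pairs: dict[str, dict[int, Any]] = {}
            for bed in sorted(Path(config.inputs["peaks_dir"]).glob("*.bed")):
                factor, stage, rep_tag = bed.stem.split(".")
                rep = int(rep_tag.removeprefix("rep"))
                ps = read_peaks_bed(bed, factor, stage, rep)
                pairs.setdefault(f"{factor}.{stage}", {})[rep] = ps
            state["datasets"] = [
                (reps[1], reps[2]) for reps in pairs.values()
            ]
        if "de" in enabled:
            cm, dd = read_count_matrix(
                config.inputs["counts"], config.inputs["design"]
            )
            state["counts"], state["design"] = cm, dd
        if "slope" in enabled:
            cm, dd = read_count_matrix(
                config.inputs["timecourse_counts"],
                config.inputs["timecourse_design"],
            )
            state["tc_counts"], state["tc_design"] = cm, dd

    # ----- screen --------------------------------------------------------
    if "screen" in enabled:
        t0 = time.time()
        logger.info("[screen] replicate intersection + enrichment screen")
        sp = ScreenParams(**config.screen)
        merged = [
            intersect_replicates(r1, r2) for r1, r2 in state["datasets"]
        ]
        results = run_screen(merged, state["age_set"], state["genes"], sp)
        df = pd.DataFrame([dataclasses.asdict(r) for r in results])
        _write_tsv(df, outdir / "screen.tsv", stage="screen",
                   **dataclasses.asdict(sp))
        state["screen_results"] = results
        record(
            "screen",
            t0,
            parameters=dataclasses.asdict(sp),
            n_datasets=len(results),
            top_hit=results[0].dataset_id,
            top_fold=round(results[0].fold, 3),
            top_p=results[0].p,
        )

    # ----- de ------------------------------------------------------------
    if "de" in enabled:
        t0 = time.time()
        logger.info("[de] rank-product differential expression (L1, L4)")
        de_tables = {}
        for stage_label, offset_key in (("L1", "de_l1"), ("L4", "de_l4")):
            rp = RankProdParams(
                **config.de, seed=config.seed + _SEED_OFFSETS[offset_key]
            )
            table = rank_product_de(
                state["counts"],
                state["design"],
                treated="treated",
                control="control",
                stage=stage_label,
                params=rp,
            )
            de_tables[stage_label] = table
            _write_tsv(
                table,
                outdir / f"de_{stage_label}.tsv",
                stage=f"de_{stage_label}",
                fdr=rp.fdr_cutoff,
                n_permutations=rp.n_permutations,
            )
        state["de_tables"] = de_tables
        record(
            "de",
            t0,
            parameters=dict(config.de),
            n_called_l1=int((de_tables["L1"]["called"] != "none").sum()),
            n_called_l4=int((de_tables["L4"]["called"] != "none").sum()),
        )

    # ----- classify ------------------------------------------------------
    if "classify" in enabled:
        t0 = time.time()
        logger.info("[classify] cross-stage concordance classes")
        p_conc = config.classify.get("p_conc", 0.05)
        assignment = classify_genes(
            stage_stats(state["de_tables"]["L1"]),
            stage_stats(state["de_tables"]["L4"]),
            p_conc,
        )
        summary = class_summary(assignment)
        _write_tsv(
            assignment.table.reset_index(),
            outdir / "classes.tsv",
            stage="classify",
            p_conc=p_conc,
        )
        _write_tsv(summary, outdir / "class_summary.tsv", stage="classify")
        state["assignment"] = assignment
        record(
            "classify",
            t0,
            parameters={"p_conc": p_conc},
            counts={
                r.gene_class: int(r.count) for r in summary.itertuples()
            },
        )

    # ----- slope ---------------------------------------------------------
    if "slope" in enabled:
        t0 = time.time()
        logger.info("[slope] attenuation slope analysis")
        slp = SlopeParams(**config.slope)
        tissues = None
        if "tc_truth" in state:
            truth = state["tc_truth"]
            tissues = {}
            for tissue in truth.attenuation_by_tissue:
                tissues[tissue] = [
                    g
                    for g, t in truth.tissue_of_gene.items()
                    if t == tissue
                ]
        overall, per_tissue = attenuation_analysis(
            state["tc_counts"],
            state["tc_design"],
            params=slp,
            tissues=tissues,
        )
        fit_rows = pd.DataFrame(
            [dataclasses.asdict(f) for f in overall.fits]
        )
        _write_tsv(fit_rows, outdir / "slope_fits.tsv", stage="slope",
                   **dataclasses.asdict(slp))
        summary_rows = [
            {
                "scope": "all",
                "mean_slope": overall.mean_slope,
                "ci_lo": overall.ci95[0],
                "ci_hi": overall.ci95[1],
                "p_vs_one": overall.p_vs_one,
                "n_replicates": overall.n_replicates,
            }
        ]
        for tissue, summ in per_tissue.items():
            summary_rows.append(
                {
                    "scope": tissue,
                    "mean_slope": summ.mean_slope,
                    "ci_lo": summ.ci95[0],
                    "ci_hi": summ.ci95[1],
                    "p_vs_one": summ.p_vs_one,
                    "n_replicates": summ.n_replicates,
                }
            )
        _write_tsv(
            pd.DataFrame(summary_rows),
            outdir / "slope_summary.tsv",
            stage="slope",
        )
        state["slope_summary"] = overall
        state["tissue_summaries"] = per_tissue
        record(
            "slope",
            t0,
            parameters=dataclasses.asdict(slp),
            mean_slope=round(overall.mean_slope, 4),
            ci95=[round(v, 4) for v in overall.ci95],
            p_vs_one=overall.p_vs_one,
        )

    # ----- trajectory ----------------------------------------------------
    if "trajectory" in enabled:
        t0 = time.time()
        logger.info("[trajectory] developmental trajectory summary")
        if "simulate" in enabled:
            expr = synthetic_data.simulate_trajectory_matrix(
                n_genes=min(sim_cfg.n_genes, 2000), seed=config.seed
            )
        else:
            expr = pd.read_csv(
                config.inputs["expr"], sep="\t", comment="#", index_col=0
            )
        traj = normalize_to_baseline(expr, scale="linear", pseudocount=0.5)
        summary = direction_summary(traj)
        _write_tsv(
            traj.reset_index().rename(columns={"index": "gene_id"}),
            outdir / "trajectory.tsv",
            stage="trajectory",
        )
        record("trajectory", t0, direction_summary=summary)

    # input checksums over everything written/read in outdir
    report["input_checksums"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
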