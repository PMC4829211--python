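"""Readers and writers for the plain-text formats the pipeline touches.

Coordinate conventions
----------------------
All intervals are 0-based, half-open ``[start, end)`` (standard BED).  The
transcription start site (TSS) of a ``+``-strand gene is its ``start``; for a
``-``-strand gene it is its ``end`` (the half-open right edge).  Peak summits
(position of maximum read density) are single base positions with
``start <= summit < end``.

Supported formats
-----------------
* BED3 / BED6(+summit-offset) for ChIP-seq peaks.  If a 7th column is
  present it is interpreted as the summit offset relative to ``start``;
  otherwise the summit defaults to the interval midpoint.
* TSV for gene models (``gene_id  chrom  start  end  strand``), count
  matrices (first column ``gene_id``, remaining columns sample ids), sample
  designs, and gene sets (one id per line, ``#`` comments allowed).

All writers emit a commented provenance header (tool version + parameters);
all readers skip ``#``-prefixed lines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-")


class FormatError(ValueError):
    """A malformed input file (bad coordinates, duplicate ids, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene record with strand-aware TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise FormatError(
                f"gene {self.gene_id}: strand must be one of {VALID_STRANDS}, "
                f"got {self.strand!r}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on ``+``, ``end`` on ``-``."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak interval with a summit position."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"peak: start >= end ([{self.start}, {self.end}))")
        if not (self.start <= self.summit < self.end):
            raise FormatError(
                f"peak [{self.start}, {self.end}): summit {self.summit} "
                "outside interval"
            )


@dataclass
class PeakSet:
    """Peaks for one dataset (factor x stage x replicate)."""

    factor: str
    stage: str
    replicate: int
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def sorted(self) -> "PeakSet":
        return PeakSet(
            self.factor,
            self.stage,
            self.replicate,
            sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end)),
        )

    @property
    def dataset_id(self) -> str:
        return f"{self.factor}.{self.stage}"


@dataclass
class GeneSet:
    """A named collection of gene ids (set semantics)."""

    name: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members


@dataclass
class CountMatrix:
    """Integer counts, genes x samples, backed by a pandas DataFrame."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids in count matrix: {dups[:5]}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise FormatError("count matrix contains non-integer values")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise FormatError("count matrix contains negative values")
        self.counts.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class SampleDesign:
    """Sample metadata: condition, stage/timepoint, replicate per sample."""

    table: pd.DataFrame  # index = sample_id

    REQUIRED = ("condition", "stage_or_timepoint", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample design missing columns: {missing}")
        if self.table.index.duplicated().any():
            raise FormatError("duplicate sample ids in design")
        triples = self.table[list(self.REQUIRED)]
        if triples.duplicated().any():
            raise FormatError(
                "duplicate (condition, stage_or_timepoint, replicate) triples"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def select(
        self, condition: str | None = None, stage_or_timepoint: str | None = None
    ) -> list[str]:
        """Sample ids matching the given labels, ordered by replicate."""
        t = self.table
        if condition is not None:
            t = t[t["condition"] == condition]
        if stage_or_timepoint is not None:
            t = t[t["stage_or_timepoint"] == stage_or_timepoint]
        return list(t.sort_values("replicate").index)


# ---------------------------------------------------------------------------
# provenance header
# ---------------------------------------------------------------------------


def provenance_header(**params) -> str:
    from . import __version__

    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# agingtx v{__version__}" + (f" {items}" if items else "")


# ---------------------------------------------------------------------------
# peaks (BED)
# ---------------------------------------------------------------------------


def read_peaks_bed(
    path: str | Path, factor: str, stage: str, replicate: int
) -> PeakSet:
    """Read a BED3/BED6(+summit-offset) file into a :class:`PeakSet`.

    Column 7, when present, is the summit offset relative to ``start``;
    without it the summit is the interval midpoint ``floor((start+end)/2)``.
    Column 5, when present, is kept as the peak score.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: fewer than 3 columns at line {lineno}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-integer coordinate at line {lineno}"
                ) from exc
            if start >= end:
                raise FormatError(f"{path}: start >= end at line {lineno}")
            score: float | None = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: non-numeric score at line {lineno}"
                    ) from exc
            if len(fields) >= 7 and fields[6] not in ("", "."):
                try:
                    summit = start + int(fields[6])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: non-integer summit offset at line {lineno}"
                    ) from exc
                if not (start <= summit < end):
                    raise FormatError(
                        f"{path}: summit outside interval at line {lineno}"
                    )
            else:
                summit = (start + end) // 2
            peaks.append(Peak(chrom, start, end, summit, score))
    if not peaks:
        warnings.warn(f"{path}: empty peak file", stacklevel=2)
    return PeakSet(factor=factor, stage=stage, replicate=replicate, peaks=peaks)


def write_peaks_bed(peakset: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED6+summit-offset (round-trips exactly)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            provenance_header(
                factor=peakset.factor,
                stage=peakset.stage,
                replicate=peakset.replicate,
            )
            + "\n"
        )
        for i, p in enumerate(peakset.sorted().peaks):
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t{score}\t.\t"
                f"{p.summit - p.start}\n"
            )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

GENE_MODEL_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a gene-model TSV (header: gene_id chrom start end strand)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    missing = [c for c in GENE_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicate gene_id {dups[:5]}")
    genes = [
        GeneModel(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
        )
        for r in df.itertuples()
    ]
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(n_genes=len(genes)) + "\n")
        fh.write("\t".join(GENE_MODEL_COLUMNS) + "\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# count matrices + designs
# ---------------------------------------------------------------------------


def read_count_matrix(
    path: str | Path, design_path: str | Path
) -> tuple[CountMatrix, SampleDesign]:
    """Read a counts TSV and its design sidecar, cross-validating samples."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be gene_id")
    df = df.set_index("gene_id")
    try:
        cm = CountMatrix(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc

    dd = pd.read_csv(design_path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in dd.columns:
        raise FormatError(f"{design_path}: missing sample_id column")
    design = SampleDesign(dd.set_index("sample_id"))

    counts_samples = set(cm.samples)
    design_samples = set(design.samples)
    if counts_samples != design_samples:
        only_counts = sorted(counts_samples - design_samples)
        only_design = sorted(design_samples - counts_samples)
        raise FormatError(
            f"sample mismatch between {path} and {design_path}: "
            f"counts-only={only_counts[:5]} design-only={only_design[:5]}"
        )
    return cm, design


def write_count_matrix(
    cm: CountMatrix,
    design: SampleDesign,
    counts_path: str | Path,
    design_path: str | Path,
) -> None:
    with open(counts_path, "w") as fh:
        fh.write(provenance_header(n_genes=len(cm.gene_ids)) + "\n")
        cm.counts.to_csv(fh, sep="\t", index_label="gene_id")
    with open(design_path, "w") as fh:
        fh.write(provenance_header() + "\n")
        design.table.to_csv(fh, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def read_gene_set(path: str | Path, name: str) -> GeneSet:
    """Read a one-id-per-line gene set; '#' comments and blanks ignored."""
    members: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            members.append(line)
    unique = frozenset(members)
    if len(unique) < len(members):
        warnings.warn(
            f"{path}: {len(members) - len(unique)} duplicate gene ids collapsed",
            stacklevel=2,
        )
    if not unique:
        warnings.warn(f"{path}: empty gene set", stacklevel=2)
    return GeneSet(name=name, members=unique)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(name=gene_set.name) + "\n")
        for gid in sorted(gene_set.members):
            fh.write(gid + "\n")


def gene_universe(genes: Iterable[GeneModel], name: str = "universe") -> GeneSet:
    """The set of all gene ids in an annotation."""
    return GeneSet(name=name, members=frozenset(g.gene_id for g in genes))
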