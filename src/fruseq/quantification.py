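"""Read counting over exonic regions, lnRPKM, and testability filters.

A read increments every region any of its aligned blocks overlaps by at least
one base (a read still increments a given region at most once, even when
several spliced blocks land in it). Expression is summarised as
RPKM = count * 1e9 / (region_length * total_mapped_reads), modelled on the
natural-log scale; zero-count observations are missing values, not
pseudocounted.

A region is *detected* in a sample if at least one read mapped to it.
Regions with no reads in any sample are dropped; regions where some
treatment group has no detected sample, or shows no variation, are
untestable and skipped by the per-region model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .gene_models import ExonicRegion, RegionIndex

logger = logging.getLogger(__name__)

WILDTYPE_GENOTYPES = ("CS", "Berlin")
OVEREXPRESSION_GENOTYPES = ("FruMA_OE", "FruMB_OE", "FruMC_OE")
NULL_GENOTYPES = ("fruP1_null_1", "fruP1_null_2")
GENOTYPES = WILDTYPE_GENOTYPES + OVEREXPRESSION_GENOTYPES + NULL_GENOTYPES


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    genotype: str
    sex: str
    replicate: int
    total_mapped_reads: int | None = None
    path: str | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.genotype in NULL_GENOTYPES and self.sex != "male":
            raise ValueError("fru P1 null genotypes exist only in males")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def condition(self) -> tuple[str, str]:
        """(genotype, sex) design cell."""
        return (self.genotype, self.sex)


def condition_label(genotype: str, sex: str) -> str:
    return f"{genotype}:{sex}"


@dataclass
class ExpressionMatrix:
    """Region x sample counts plus metadata and optional lnRPKM."""

    counts: pd.DataFrame            # index region_id, columns sample_id, int
    lengths: pd.Series              # region_id -> length in bases
    samples: list[SampleMeta]
    lnrpkm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if (self.lengths <= 0).any():
            raise ValueError("non-positive region length")
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != sample_ids:
            raise ValueError("counts columns do not match sample metadata order")

    @property
    def total_mapped_reads(self) -> pd.Series:
        return pd.Series(
            {s.sample_id: s.total_mapped_reads for s in self.samples},
            name="total_mapped_reads",
        )

    def sample_meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


@dataclass
class FilterReport:
    n_total: int
    n_undetected: int
    n_untestable: int
    n_testable: int

    def __post_init__(self) -> None:
        if self.n_total != self.n_undetected + self.n_untestable + self.n_testable:
            raise ValueError("FilterReport categories do not partition the total")


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def _iter_sam_blocks(path: str) -> Iterable[tuple[str, list[tuple[int, int]]]]:
    """Yield (chrom, aligned_blocks) per primary mapped record of a SAM/BAM."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            yield rec.reference_name, rec.get_blocks()


def _iter_bed_blocks(path: str) -> Iterable[tuple[str, list[tuple[int, int]]]]:
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            yield f[0], [(int(f[1]), int(f[2]))]


def count_reads(
    alignments: Mapping[str, str | Iterable[tuple[str, int, int]]],
    regions: Sequence[ExonicRegion],
    meta: Sequence[SampleMeta],
) -> ExpressionMatrix:
    """Count primary mapped reads per exonic region for every sample.

    ``alignments`` maps sample_id to a SAM/BAM path, a BED path, or an
    iterable of (chrom, start, end) read intervals. A read increments every
    region it overlaps by >= 1 base, once per region. ``total_mapped_reads``
    is taken from the sample metadata when given, else set to the number of
    primary mapped records seen.
    """
    index = RegionIndex(regions)
    region_ids = [r.region_id for r in regions]
    counts = np.zeros((len(regions), len(meta)), dtype=np.int64)
    out_meta: list[SampleMeta] = []

    for j, sample in enumerate(meta):
        src = alignments[sample.sample_id]
        if isinstance(src, (str, Path)):
            src = str(src)
            it = (
                _iter_bed_blocks(src)
                if src.endswith((".bed", ".bed.txt"))
                else _iter_sam_blocks(src)
            )
        else:
            it = ((chrom, [(s, e)]) for chrom, s, e in src)

        n_mapped = 0
        missing_chroms: set[str] = set()
        for chrom, blocks in it:
            n_mapped += 1
            if chrom not in index:
                missing_chroms.add(chrom)
                continue
            hit: set[int] = set()
            for s, e in blocks:
                hit.update(index.overlapping(chrom, s, e))
            for i in hit:
                counts[i, j] += 1
        if missing_chroms:
            logger.warning(
                "sample %s: reads on %s not counted (chrom absent from regions)",
                sample.sample_id,
                sorted(missing_chroms),
            )
        if n_mapped == 0:
            raise ValueError(f"sample {sample.sample_id} has zero mapped reads")
        total = sample.total_mapped_reads or n_mapped
        out_meta.append(replace(sample, total_mapped_reads=total))

    df = pd.DataFrame(counts, index=region_ids, columns=[s.sample_id for s in meta])
    lengths = pd.Series(
        {r.region_id: r.length for r in regions}, name="length"
    ).loc[region_ids]
    return ExpressionMatrix(counts=df, lengths=lengths, samples=out_meta)


# ---------------------------------------------------------------------------
# lnRPKM
# ---------------------------------------------------------------------------

def compute_lnrpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Attach the natural-log RPKM matrix (NaN where a count is zero)."""
    totals = matrix.total_mapped_reads
    if totals.isna().any():
        raise ValueError("total_mapped_reads missing for some samples")
    rpkm = (
        matrix.counts * 1e9
    ).div(matrix.lengths, axis=0).div(totals.astype(float), axis=1)
    lnrpkm = np.log(rpkm.where(matrix.counts > 0))
    return ExpressionMatrix(
        counts=matrix.counts,
        lengths=matrix.lengths,
        samples=matrix.samples,
        lnrpkm=lnrpkm,
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_regions(
    matrix: ExpressionMatrix,
    groups: Mapping[str, Sequence[str]],
) -> tuple[list[str], FilterReport]:
    """Partition regions into undetected / untestable / testable.

    ``groups`` maps treatment-group names to sample ids. A region is
    undetected if no read mapped in any sample of the matrix; untestable if
    some group has no detected sample, or some group's detected lnRPKM values
    show no variation (>= 2 detected observations, all identical); testable
    otherwise.
    """
    if matrix.lnrpkm is None:
        matrix = compute_lnrpkm(matrix)
    for name, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"treatment group {name!r} has fewer than 2 samples")

    detected = matrix.counts > 0
    undetected_mask = ~detected.any(axis=1)

    untestable_mask = pd.Series(False, index=matrix.counts.index)
    for name, ids in groups.items():
        ids = list(ids)
        grp_det = detected[ids]
        n_det = grp_det.sum(axis=1)
        no_detection = n_det == 0
        vals = matrix.lnrpkm[ids]
        spread = vals.max(axis=1) - vals.min(axis=1)
        no_variation = (n_det >= 2) & (spread.fillna(0.0) == 0.0)
        untestable_mask |= no_detection | no_variation
    untestable_mask &= ~undetected_mask

    testable = matrix.counts.index[~undetected_mask & ~untestable_mask]
    report = FilterReport(
        n_total=len(matrix.counts),
        n_undetected=int(undetected_mask.sum()),
        n_untestable=int(untestable_mask.sum()),
        n_testable=len(testable),
    )
    return list(testable), report


# ---------------------------------------------------------------------------
# Sample sheet / table IO
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a TSV sample sheet (sample_id, genotype, sex, replicate[, path,
    total_mapped_reads])."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                genotype=str(row.genotype),
                sex=str(row.sex),
                replicate=int(row.replicate),
                total_mapped_reads=(
                    int(row.total_mapped_reads)
                    if "total_mapped_reads" in df.columns
                    and not pd.isna(row.total_mapped_reads)
                    else None
                ),
                path=str(row.path) if "path" in df.columns else None,
            )
        )
    return out


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("region_id").to_csv(path, sep="\t")


def write_lnrpkm(matrix: ExpressionMatrix, path: str | Path) -> None:
    if matrix.lnrpkm is None:
        raise ValueError("lnrpkm not computed")
    matrix.lnrpkm.rename_axis("region_id").to_csv(path, sep="\t", na_rep="NA")
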