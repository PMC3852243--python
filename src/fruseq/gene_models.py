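"""Gene models and maximal exonic regions.

Annotated exons from different isoforms (and occasionally different genes)
overlap. For exon-level expression testing the overlapping exons are combined,
regardless of strand, into *maximal exonic regions*: connected components of
the interval-overlap graph over all annotated exons. Regions formed from a
single distinct exon are labelled ``S####_SI``, regions combining several
distinct exons ``F####_SI``. Within one gene a region is further classified as

- ``constitutive`` — a single identical exon present in every isoform,
- ``common``       — overlapped by every isoform, but with differing exon
                     boundaries (or several exons combined),
- ``alternative``  — absent from at least one isoform.

Regions combining exons of more than one gene are flagged ``cross_gene`` and
classified ``unclassified``; they are excluded from downstream testing.

All internal coordinates are 0-based half-open; GFF3/GTF input (1-based
inclusive) is converted on read. Two intervals overlap iff they share at
least one base; bookended (touching) intervals do not merge.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

logger = logging.getLogger(__name__)

#: Chromosome arms recognised for arm-level enrichment.
ARM_NAMES = ("X", "2L", "2R", "3L", "3R", "4")

CLASS_CONSTITUTIVE = "constitutive"
CLASS_COMMON = "common"
CLASS_ALTERNATIVE = "alternative"
CLASS_UNCLASSIFIED = "unclassified"


def chrom_to_arm(chrom: str) -> str:
    """Map a sequence name to a chromosome arm label (``other`` if unknown)."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return name if name in ARM_NAMES else "other"


@dataclass(frozen=True)
class Isoform:
    """One transcript isoform: an ordered list of non-overlapping exons."""

    isoform_id: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted by start

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"isoform {self.isoform_id} has no exons")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"isoform {self.isoform_id}: exons ({s1},{e1}) and "
                    f"({s2},{e2}) overlap"
                )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    isoforms: tuple[Isoform, ...]
    symbol: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.isoforms:
            raise ValueError(f"gene {self.gene_id} has no isoforms")

    @property
    def arm(self) -> str:
        return chrom_to_arm(self.chrom)

    @property
    def span(self) -> tuple[int, int]:
        starts = [e[0] for iso in self.isoforms for e in iso.exons]
        ends = [e[1] for iso in self.isoforms for e in iso.exons]
        return min(starts), max(ends)


@dataclass(frozen=True)
class ExonicRegion:
    """A maximal exonic region: union span of a connected exon component."""

    region_id: str
    chrom: str
    start: int
    end: int
    #: full provenance: (gene_id, isoform_id, exon_start, exon_end)
    source_exons: tuple[tuple[str, str, int, int], ...]
    classification: str

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(g for g, _, _, _ in self.source_exons)

    @property
    def n_source_exons(self) -> int:
        """Number of *distinct* exon intervals combined into the region."""
        return len({(s, e) for _, _, s, e in self.source_exons})

    @property
    def cross_gene(self) -> bool:
        return len(self.gene_ids) > 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OverlapSummary:
    """Partition of a finished region set into the three overlap categories."""

    n_singleton: int = 0           # single distinct exon
    n_alt_start_end: int = 0       # several exons of one gene combined
    n_cross_gene: int = 0          # exons from >1 gene combined

    @property
    def total(self) -> int:
        return self.n_singleton + self.n_alt_start_end + self.n_cross_gene


# ---------------------------------------------------------------------------
# Annotation reading
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def _looks_like_gtf(text: str) -> bool:
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) >= 9:
            return "gene_id \"" in fields[8] or "transcript_id \"" in fields[8]
    return False


def read_gene_models(source: str | Path) -> list[GeneModel]:
    """Parse GFF3 or GTF annotation into :class:`GeneModel` objects.

    ``source`` may be a path or the annotation text itself. Both attribute
    dialects (GFF3 ``ID``/``Parent`` and GTF ``gene_id``/``transcript_id``)
    are accepted; for GTF, gene and transcript features are inferred from the
    exon lines when absent. Features other than gene/transcript/exon are
    ignored. Coordinates are converted from 1-based inclusive to the internal
    0-based half-open convention.
    """
    text: str
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)

    is_gtf = _looks_like_gtf(text)
    db = gffutils.create_db(
        text,
        ":memory:",
        from_string=True,
        force_gff=not is_gtf,
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=not is_gtf,
        disable_infer_transcripts=not is_gtf,
    )

    # every exon must resolve to a transcript parent
    for exon in db.features_of_type("exon"):
        if not list(db.parents(exon, featuretype=_TRANSCRIPT_TYPES, level=1)):
            raise ValueError(f"exon without resolvable parent: {exon}")

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        isoforms = []
        for tx in db.children(gene, featuretype=_TRANSCRIPT_TYPES, level=1):
            exons = tuple(
                (e.start - 1, e.end)
                for e in db.children(tx, featuretype="exon", order_by="start")
            )
            if exons:
                isoforms.append(Isoform(isoform_id=tx.id, exons=exons))
        if not isoforms:
            logger.warning("gene %s has no transcripts with exons; skipped", gene.id)
            continue
        if gene.strand not in ("+", "-"):
            raise ValueError(f"gene {gene.id}: unknown strand symbol {gene.strand!r}")
        symbol = None
        for key in ("Name", "gene_symbol", "gene_name"):
            if key in gene.attributes:
                symbol = gene.attributes[key][0]
                break
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                isoforms=tuple(isoforms),
                symbol=symbol,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------

def classify_region(
    source_exons: Sequence[tuple[str, str, int, int]],
    genes_by_id: Mapping[str, GeneModel],
) -> str:
    """Classify a region's exon component within its gene.

    Returns ``unclassified`` for cross-gene components (the classification is
    only defined within a single gene).
    """
    gene_ids = {g for g, _, _, _ in source_exons}
    if len(gene_ids) != 1:
        return CLASS_UNCLASSIFIED
    gene = genes_by_id[next(iter(gene_ids))]
    all_isoforms = {iso.isoform_id for iso in gene.isoforms}
    contributing = {i for _, i, _, _ in source_exons}
    distinct_exons = {(s, e) for _, _, s, e in source_exons}
    if len(distinct_exons) == 1 and contributing == all_isoforms:
        return CLASS_CONSTITUTIVE
    if contributing == all_isoforms:
        return CLASS_COMMON
    return CLASS_ALTERNATIVE


def build_exonic_regions(
    genes: Iterable[GeneModel],
) -> tuple[list[ExonicRegion], OverlapSummary]:
    """Flatten all exons of ``genes`` into maximal exonic regions.

    Exons are pooled across genes and strands; connected components under
    strict interval overlap (>= 1 shared base) become one region spanning the
    component's union. Region ids are assigned in (chrom, start) sort order,
    1-based, zero-padded; ``S`` if the region holds a single distinct exon,
    ``F`` otherwise.
    """
    genes = list(genes)
    genes_by_id = {g.gene_id: g for g in genes}
    if len(genes_by_id) != len(genes):
        raise ValueError("duplicate gene_id in input")

    records: list[tuple[str, int, int, str, str]] = []
    for g in genes:
        for iso in g.isoforms:
            for s, e in iso.exons:
                records.append((g.chrom, s, e, g.gene_id, iso.isoform_id))
    records.sort(key=lambda r: (r[0], r[1], r[2]))

    components: list[tuple[str, int, int, list[tuple[str, str, int, int]]]] = []
    for chrom, s, e, gid, iid in records:
        if components and components[-1][0] == chrom and s < components[-1][2]:
            c, cs, ce, members = components[-1]
            members.append((gid, iid, s, e))
            components[-1] = (c, cs, max(ce, e), members)
        else:
            components.append((chrom, s, e, [(gid, iid, s, e)]))

    pad = max(4, len(str(len(components))))
    regions: list[ExonicRegion] = []
    summary = OverlapSummary()
    for idx, (chrom, start, end, members) in enumerate(components, start=1):
        source = tuple(members)
        n_distinct = len({(s, e) for _, _, s, e in source})
        n_genes = len({g for g, _, _, _ in source})
        prefix = "S" if n_distinct == 1 else "F"
        region = ExonicRegion(
            region_id=f"{prefix}{idx:0{pad}d}_SI",
            chrom=chrom,
            start=start,
            end=end,
            source_exons=source,
            classification=classify_region(source, genes_by_id),
        )
        regions.append(region)
        if n_distinct == 1:
            summary.n_singleton += 1
        elif n_genes > 1:
            summary.n_cross_gene += 1
        else:
            summary.n_alt_start_end += 1
    return regions, summary


# ---------------------------------------------------------------------------
# Lookups and output
# ---------------------------------------------------------------------------

class RegionIndex:
    """Overlap lookup over a finished (non-overlapping) region set."""

    def __init__(self, regions: Sequence[ExonicRegion]):
        self.regions = list(regions)
        self._by_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
        per_chrom: dict[str, list[int]] = {}
        for i, r in enumerate(self.regions):
            per_chrom.setdefault(r.chrom, []).append(i)
        for chrom, idxs in per_chrom.items():
            idxs.sort(key=lambda i: self.regions[i].start)
            starts = [self.regions[i].start for i in idxs]
            ends = [self.regions[i].end for i in idxs]
            self._by_chrom[chrom] = (starts, ends, idxs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._by_chrom

    def overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        """Indices of regions overlapping [start, end) by >= 1 base."""
        if chrom not in self._by_chrom or end <= start:
            return []
        starts, ends, idxs = self._by_chrom[chrom]
        lo = bisect_right(ends, start)
        hi = bisect_left(starts, end)
        return [idxs[i] for i in range(lo, hi)]


def region_to_gene_map(regions: Iterable[ExonicRegion]) -> dict[str, str]:
    """region_id -> gene_id for single-gene regions (cross-gene excluded)."""
    return {
        r.region_id: next(iter(r.gene_ids))
        for r in regions
        if not r.cross_gene
    }


def write_regions_bed(regions: Iterable[ExonicRegion], path: str | Path) -> None:
    """Write regions as BED6+ (extra columns: classification, gene_ids, cross_gene)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        r.region_id,
                        str(r.n_source_exons),
                        ".",
                        r.classification,
                        ",".join(sorted(r.gene_ids)),
                        str(int(r.cross_gene)),
                    ]
                )
                + "\n"
            )


def write_overlap_summary(summary: OverlapSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tcount\n")
        fh.write(f"singleton\t{summary.n_singleton}\n")
        fh.write(f"alt_start_end\t{summary.n_alt_start_end}\n")
        fh.write(f"cross_gene\t{summary.n_cross_gene}\n")
        fh.write(f"total\t{summary.total}\n")
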