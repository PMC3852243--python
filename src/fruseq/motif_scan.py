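"""Genome-wide motif scanning over gene scan regions.

Each gene's scan region is its annotated span extended by 2 kb on both
sides (clipped to the chromosome), covering the putative regulatory region
and the entire genic region, introns included. Two scanning modes:

- ``exact_word``: a window hits iff it equals the consensus word (plus
  strand) or its reverse complement (minus strand);
- ``pwm_threshold``: a window hits iff its log-odds score is at least
  ``threshold_fraction`` times the motif's maximum achievable score.

Both strands are always scanned; windows containing N are skipped. Hit
counts are deliberately not normalised for region length; the gene x motif
table records the raw count and a presence flag (count >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_models import GeneModel
from .selex_motif import MotifModel, revcomp

DEFAULT_FLANK = 2000
MODE_EXACT = "exact_word"
MODE_PWM = "pwm_threshold"

_SCAN_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class ScanRegion:
    gene_id: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_id: str
    chrom: str
    position: int          # genomic, 0-based start of the matched window
    end: int               # genomic end (position + motif width)
    strand: str
    score: float            # log-odds of the matched window


def make_scan_regions(
    genes: Iterable[GeneModel],
    chrom_lengths: Mapping[str, int],
    flank: int = DEFAULT_FLANK,
) -> list[ScanRegion]:
    """One scan region per gene: span +/- flank, clipped to the chromosome."""
    out = []
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise ValueError(f"gene {g.gene_id}: chrom {g.chrom!r} absent from genome")
        s, e = g.span
        out.append(
            ScanRegion(
                gene_id=g.gene_id,
                chrom=g.chrom,
                start=max(0, s - flank),
                end=min(chrom_lengths[g.chrom], e + flank),
            )
        )
    return out


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.fromiter(
            (_SCAN_INDEX[b] for b in sequence.upper()), dtype=np.int64
        )
    except KeyError as exc:
        raise ValueError(f"unexpected base in sequence: {exc}") from exc


def scan_sequence(
    sequence: str,
    motif: MotifModel,
    mode: str = MODE_EXACT,
    threshold_fraction: float = 0.85,
    motif_id: str = "motif",
    gene_id: str = "",
    chrom: str = "",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan one sequence on both strands; hit positions are window starts.

    ``offset`` shifts reported positions into genomic coordinates. Hits come
    back in ascending position, plus strand before minus at equal position.
    """
    w = motif.width
    if len(sequence) < w:
        return []
    arr = _encode(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(arr, w)
    valid = ~(windows == 4).any(axis=1)
    cols = np.arange(w)

    if mode == MODE_EXACT:
        fwd = _encode(motif.consensus)
        rev = _encode(revcomp(motif.consensus))
        plus = valid & (windows == fwd).all(axis=1)
        minus = valid & (windows == rev).all(axis=1)
        full = motif.max_score
        score_plus = np.full(len(windows), full)
        score_minus = np.full(len(windows), full)
    elif mode == MODE_PWM:
        lo = motif.log_odds
        lo_rc = lo[::-1, ::-1]  # reverse-complement scoring matrix
        safe = np.where(windows == 4, 0, windows)
        score_plus = lo[safe, cols].sum(axis=1)
        score_minus = lo_rc[safe, cols].sum(axis=1)
        threshold = threshold_fraction * motif.max_score
        plus = valid & (score_plus >= threshold)
        minus = valid & (score_minus >= threshold)
    else:
        raise ValueError(f"unknown scan mode {mode!r}")

    hits = [
        (int(p), "+", float(score_plus[p])) for p in np.flatnonzero(plus)
    ] + [
        (int(p), "-", float(score_minus[p])) for p in np.flatnonzero(minus)
    ]
    hits.sort(key=lambda h: (h[0], h[1]))
    return [
        MotifHit(
            gene_id=gene_id,
            motif_id=motif_id,
            chrom=chrom,
            position=offset + p,
            end=offset + p + w,
            strand=strand,
            score=score,
        )
        for p, strand, score in hits
    ]


def scan_gene_regions(
    genome: Mapping[str, str],
    scan_regions: Sequence[ScanRegion],
    motifs: Mapping[str, MotifModel],
    mode: str = MODE_EXACT,
    threshold_fraction: float = 0.85,
) -> list[MotifHit]:
    """Scan every gene's region for every motif."""
    hits: list[MotifHit] = []
    for region in scan_regions:
        seq = genome[region.chrom][region.start : region.end]
        for motif_id, motif in motifs.items():
            hits.extend(
                scan_sequence(
                    seq,
                    motif,
                    mode=mode,
                    threshold_fraction=threshold_fraction,
                    motif_id=motif_id,
                    gene_id=region.gene_id,
                    chrom=region.chrom,
                    offset=region.start,
                )
            )
    return hits


def build_gene_motif_table(
    hits: Iterable[MotifHit],
    gene_ids: Sequence[str],
    motif_ids: Sequence[str],
) -> pd.DataFrame:
    """Gene x motif hit-count table (attrs['presence'] holds the booleans)."""
    counts = pd.DataFrame(0, index=list(gene_ids), columns=list(motif_ids))
    for h in hits:
        counts.loc[h.gene_id, h.motif_id] += 1
    counts.index.name = "gene_id"
    counts.attrs["presence"] = counts >= 1
    return counts


def presence(table: pd.DataFrame) -> pd.DataFrame:
    return table >= 1


def write_hits_bed(hits: Iterable[MotifHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.position}\t{h.end}\t"
                f"{h.gene_id}|{h.motif_id}\t{round(h.score * 100)}\t{h.strand}\n"
            )


def write_gene_motif_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
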