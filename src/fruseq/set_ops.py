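"""Venn algebra over condition gene sets and list-overlap association.

Supports the bookkeeping around the differential-expression output: counting
every membership pattern among two or three gene sets, and testing whether
two gene lists (e.g. over-expression-induced vs loss-of-function-induced)
are associated over the shared gene universe.
"""

from __future__ import annotations

from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

from .enrichment import ContingencyResult, GeneSet, enrichment_test


def venn_counts(sets: Sequence[GeneSet]) -> dict[tuple[bool, ...], int]:
    """Count genes in every non-empty membership pattern of 2 or 3 sets.

    The pattern ``(True, False)`` means "in the first set only". Counts over
    all patterns sum to the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    union = set().union(*(s.members for s in sets))
    counts: dict[tuple[bool, ...], int] = {
        pattern: 0
        for pattern in product((True, False), repeat=len(sets))
        if any(pattern)
    }
    for gene in union:
        pattern = tuple(gene in s.members for s in sets)
        counts[pattern] += 1
    return counts


def overlap_association(
    set_a: GeneSet, set_b: GeneSet
) -> ContingencyResult:
    """2x2 association between membership in two sets over the universe."""
    return enrichment_test(set_a, set_b)


def read_gene_set(path: str | Path, universe_size: int, name: str | None = None) -> GeneSet:
    members = frozenset(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )
    return GeneSet(name=name or Path(path).stem, members=members, universe_size=universe_size)


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def write_venn_counts(counts: dict[tuple[bool, ...], int], names: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\tcount\n")
        for pattern in sorted(counts, reverse=True):
            flags = "\t".join("1" if x else "0" for x in pattern)
            fh.write(f"{flags}\t{counts[pattern]}\n")
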