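"""2x2 enrichment statistics for gene sets, chromosome arms, and motif pairs.

Every test reduces to a 2x2 contingency table over a fixed gene universe:
(in set / not in set) x (has property / lacks property). The table is
summarised with expected counts (row x column margins / N), the Pearson
chi-square without continuity correction, its chi-square-distribution tail
p-value (df = 1), and the two-tailed Fisher exact p (point-probability
method: the sum over all margin-fixed tables whose hypergeometric point
probability does not exceed the observed one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    universe_size: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if self.universe_size < len(self.members):
            raise ValueError(
                f"gene set {self.name!r}: universe smaller than the set"
            )

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ContingencyResult:
    """A 2x2 table [[a, b], [c, d]] with its enrichment statistics."""

    table: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p_chi: float
    p_fisher_two_tail: float
    odds_ratio: float

    @property
    def n(self) -> int:
        return int(self.table.sum())


def contingency_from_sets(
    gene_set: GeneSet | Iterable[str],
    property_genes: GeneSet | Iterable[str],
    universe_size: int | None = None,
) -> np.ndarray:
    """Build the 2x2 table (in set x has property) over the universe."""
    if isinstance(gene_set, GeneSet) and isinstance(property_genes, GeneSet):
        if gene_set.universe_size != property_genes.universe_size:
            raise ValueError("gene sets disagree on universe size")
        universe_size = universe_size or gene_set.universe_size
    if universe_size is None:
        raise ValueError("universe_size required")
    s = set(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    p = set(
        property_genes.members
        if isinstance(property_genes, GeneSet)
        else property_genes
    )
    a = len(s & p)
    b = len(s) - a
    c = len(p) - a
    d = universe_size - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent inputs: negative derived cell")
    return np.array([[a, b], [c, d]], dtype=np.int64)


def expected_counts(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    n = table.sum()
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / n


def chisq_test(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction, df = 1."""
    exp = expected_counts(table)
    if (exp == 0).any():
        raise ValueError("zero expected cell; use the Fisher exact test")
    chi2 = float(((np.asarray(table, dtype=float) - exp) ** 2 / exp).sum())
    return chi2, 1, float(stats.chi2.sf(chi2, df=1))


def fisher_exact_test(table: np.ndarray) -> tuple[float, float]:
    """Two-tailed Fisher exact p (point-probability method) and odds ratio."""
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), float(odds)


def analyze_table(table: np.ndarray) -> ContingencyResult:
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    exp = expected_counts(table)
    p_fisher, odds = fisher_exact_test(table)
    if (exp == 0).any():
        chi2, p_chi = float("nan"), float("nan")
    else:
        chi2, _, p_chi = chisq_test(table)
    return ContingencyResult(
        table=table,
        expected=exp,
        chi2=chi2,
        df=1,
        p_chi=p_chi,
        p_fisher_two_tail=p_fisher,
        odds_ratio=odds,
    )


def enrichment_test(
    gene_set: GeneSet,
    property_genes: GeneSet,
    universe_size: int | None = None,
) -> ContingencyResult:
    """Enrichment of a property (e.g. motif presence) within a gene set."""
    table = contingency_from_sets(gene_set, property_genes, universe_size)
    if table[0].sum() == 0:
        raise ValueError("empty gene set: the test is undefined")
    return analyze_table(table)


def recover_property_total(
    set_size: int, expected_in_set: float, universe_size: int
) -> float:
    """Invert expected = set_size * M / N for the property total M.

    Used to reconstruct genome-wide motif-positive gene counts from a
    published expected count; a trustworthy reconstruction is (near-)integral.
    """
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    return expected_in_set * universe_size / set_size


# ---------------------------------------------------------------------------
# Chromosome-arm enrichment
# ---------------------------------------------------------------------------

def chromosome_enrichment(
    gene_set: Iterable[str],
    gene_to_arm: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-arm 2x2 enrichment of a gene set over the mapped universe.

    The universe is all genes in ``gene_to_arm``; set members without an arm
    assignment are excluded (their count is reported in the ``n_unmapped``
    attribute of the returned frame). Arms with Fisher p < alpha are flagged
    enriched or depleted by the sign of observed - expected.
    """
    universe = set(gene_to_arm)
    members = set(gene_set)
    unmapped = members - universe
    members &= universe
    n = len(universe)

    rows = []
    arms = sorted({gene_to_arm[g] for g in universe})
    for arm in arms:
        on_arm = {g for g in universe if gene_to_arm[g] == arm}
        table = contingency_from_sets(members, on_arm, n)
        res = analyze_table(table)
        observed = int(table[0, 0])
        expected = len(members) * len(on_arm) / n
        direction = "enriched" if observed > expected else "depleted"
        rows.append(
            {
                "arm": arm,
                "arm_size": len(on_arm),
                "observed": observed,
                "expected": expected,
                "chi2": res.chi2,
                "p_fisher": res.p_fisher_two_tail,
                "odds_ratio": res.odds_ratio,
                "direction": direction,
                "significant": res.p_fisher_two_tail < alpha,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_unmapped"] = len(unmapped)
    return out


# ---------------------------------------------------------------------------
# Motif co-occurrence
# ---------------------------------------------------------------------------

def motif_cooccurrence(presence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise association between motif presence columns over all genes.

    ``presence`` is a boolean gene x motif frame. Returns one row per
    unordered motif pair with the 2x2 cells, Fisher two-tail p and odds
    ratio.
    """
    motifs = list(presence.columns)
    if len(motifs) < 2:
        raise ValueError("need at least two motifs")
    rows = []
    for i, m1 in enumerate(motifs):
        for m2 in motifs[i + 1 :]:
            x = presence[m1].astype(bool)
            y = presence[m2].astype(bool)
            table = np.array(
                [
                    [int((x & y).sum()), int((x & ~y).sum())],
                    [int((~x & y).sum()), int((~x & ~y).sum())],
                ]
            )
            res = analyze_table(table)
            rows.append(
                {
                    "motif_a": m1,
                    "motif_b": m2,
                    "both": table[0, 0],
                    "only_a": table[0, 1],
                    "only_b": table[1, 0],
                    "neither": table[1, 1],
                    "odds_ratio": res.odds_ratio,
                    "p_fisher": res.p_fisher_two_tail,
                }
            )
    return pd.DataFrame(rows)


def write_enrichment_table(
    results: Sequence[tuple[str, int, ContingencyResult]], path
) -> None:
    """Write rows of (label, set size, result) in the published table layout."""
    with open(path, "w") as fh:
        fh.write(
            "label\ttotal_genes\tset_size\tobserved\texpected\tchi2\tdf\t"
            "p_chi\tp_fisher_two_tail\n"
        )
        for label, set_size, r in results:
            fh.write(
                f"{label}\t{r.n}\t{set_size}\t{r.table[0, 0]}\t"
                f"{r.expected[0, 0]:.7f}\t{r.chi2:.7f}\t{r.df}\t"
                f"{r.p_chi:.6g}\t{r.p_fisher_two_tail:.6g}\n"
            )
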