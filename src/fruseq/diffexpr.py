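"""Per-region linear models, pooled FDR correction, and compound DE calls.

Each exonic region is fit separately with a one-way fixed-effect model on the
(genotype, sex) design cells of its non-missing lnRPKM observations. Every
comparison of interest is a contrast (difference of cell means) in that single
model, with a t-statistic built on the pooled residual variance across all
cells; Benjamini-Hochberg FDR correction is applied once to the pooled vector
of raw p-values across all regions and all contrasts.

Calling is deliberately conservative about strain background: an
over-expression region is called only if it differs from BOTH wild-type
strains (CS and Berlin) of the matching sex — significant (FDR p < 0.20),
>= 2-fold, same direction in both comparisons. Loss-of-function calls require
all four comparisons (2 fru-null allele combinations x 2 wild types) to be
significant with agreeing direction, with no fold-change gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantification import (
    ExpressionMatrix,
    NULL_GENOTYPES,
    OVEREXPRESSION_GENOTYPES,
    WILDTYPE_GENOTYPES,
    condition_label,
)

FAMILY_OVEREXPRESSION = "overexpression_vs_wt"
FAMILY_NULL = "null_vs_wt"

DEFAULT_FDR_THRESHOLD = 0.20
DEFAULT_FC_THRESHOLD = 2.0


@dataclass(frozen=True)
class ContrastSpec:
    """A named difference between two design cells (group_a - group_b)."""

    name: str
    group_a: str  # condition label "genotype:sex"
    group_b: str
    family: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")
        if self.family not in (FAMILY_OVEREXPRESSION, FAMILY_NULL):
            raise ValueError(f"unknown contrast family {self.family!r}")


def default_contrasts(
    genotypes_present: Sequence[tuple[str, str]],
) -> list[ContrastSpec]:
    """Build the standard contrast battery for the design cells present.

    Over-expressors are compared to both wild types of the same sex; fru-null
    males to both wild-type male strains.
    """
    cells = set(genotypes_present)
    out: list[ContrastSpec] = []
    for g in OVEREXPRESSION_GENOTYPES:
        for sex in ("male", "female"):
            if (g, sex) not in cells:
                continue
            for wt in WILDTYPE_GENOTYPES:
                if (wt, sex) in cells:
                    out.append(
                        ContrastSpec(
                            name=f"{g}_{sex}_vs_{wt}",
                            group_a=condition_label(g, sex),
                            group_b=condition_label(wt, sex),
                            family=FAMILY_OVEREXPRESSION,
                        )
                    )
    for g in NULL_GENOTYPES:
        if (g, "male") not in cells:
            continue
        for wt in WILDTYPE_GENOTYPES:
            if (wt, "male") in cells:
                out.append(
                    ContrastSpec(
                        name=f"{g}_vs_{wt}",
                        group_a=condition_label(g, "male"),
                        group_b=condition_label(wt, "male"),
                        family=FAMILY_NULL,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def fit_region_model(
    values: pd.Series,
    cells: pd.Series,
    contrasts: Sequence[ContrastSpec],
) -> list[dict]:
    """Fit the one-way cell-means model for one region and test contrasts.

    ``values`` holds lnRPKM observations indexed by sample id (NaN =
    missing); ``cells`` maps sample id to its design-cell label. Returns one
    record per contrast with the estimate, fold change, raw p, and a reason
    string when the contrast had to be skipped.
    """
    obs = values.dropna()
    labels = cells.loc[obs.index]
    grouped = obs.groupby(labels)
    means = grouped.mean()
    ns = grouped.size()
    sse = float(((obs - means.loc[labels].values) ** 2).sum())
    df_resid = int(len(obs) - len(means))

    out = []
    for c in contrasts:
        rec = {
            "contrast": c.name,
            "family": c.family,
            "estimate": np.nan,
            "fold_change": np.nan,
            "raw_p": np.nan,
            "reason": "",
        }
        if c.group_a not in means.index or c.group_b not in means.index:
            rec["reason"] = "all-missing group"
            out.append(rec)
            continue
        if df_resid < 1:
            rec["reason"] = "zero residual df"
            out.append(rec)
            continue
        s2 = sse / df_resid
        est = float(means[c.group_a] - means[c.group_b])
        se = np.sqrt(s2 * (1.0 / ns[c.group_a] + 1.0 / ns[c.group_b]))
        if se == 0.0:
            p = 1.0 if est == 0.0 else 0.0
        else:
            t = est / se
            p = float(2.0 * stats.t.sf(abs(t), df_resid))
        rec.update(estimate=est, fold_change=float(np.exp(est)), raw_p=p)
        out.append(rec)
    return out


def run_de(
    matrix: ExpressionMatrix,
    contrasts: Sequence[ContrastSpec],
    testable_regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fit every testable region and return the pooled, FDR-corrected table.

    Columns: region_id, contrast, family, estimate, fold_change, raw_p,
    fdr_p, reason (non-empty when a contrast was skipped).
    """
    if matrix.lnrpkm is None:
        raise ValueError("run compute_lnrpkm first")
    cells = pd.Series(
        {s.sample_id: condition_label(*s.condition) for s in matrix.samples}
    )
    region_ids = (
        list(testable_regions)
        if testable_regions is not None
        else list(matrix.lnrpkm.index)
    )
    rows = []
    for rid in region_ids:
        for rec in fit_region_model(matrix.lnrpkm.loc[rid], cells, contrasts):
            rows.append({"region_id": rid, **rec})
    results = pd.DataFrame(rows)
    return fdr_correct(results)


def fdr_correct(results: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg step-up applied ONCE across all regions and contrasts."""
    results = results.copy()
    results["fdr_p"] = np.nan
    mask = results["raw_p"].notna()
    if mask.any():
        _, adj, _, _ = multipletests(
            results.loc[mask, "raw_p"].values, method="fdr_bh"
        )
        results.loc[mask, "fdr_p"] = adj
    return results


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def _passes(
    row: pd.Series,
    fdr_threshold: float,
    fc_threshold: float | None,
) -> bool:
    if pd.isna(row["fdr_p"]) or row["fdr_p"] >= fdr_threshold:
        return False
    if fc_threshold is not None and abs(row["estimate"]) < np.log(fc_threshold):
        return False
    return True


def call_differential(
    results: pd.DataFrame,
    conditions: Mapping[str, Sequence[str]],
    family: str,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Apply the compound gating rules and emit induced/repressed calls.

    ``conditions`` maps a condition name to the list of contrast names that
    must ALL pass for a region to be called under that condition (two
    wild-type comparisons for an over-expressor, four for the
    loss-of-function family). The fold-change gate applies only to the
    over-expression family. Direction must agree across the required
    contrasts; positive estimates are induced.

    Returns a frame with columns region_id, condition, status, and a second
    frame is not produced: regions lacking a required contrast are skipped
    (reason retained in ``results``).
    """
    fc: float | None = fc_threshold if family == FAMILY_OVEREXPRESSION else None
    by_region = results.set_index(["region_id", "contrast"]).sort_index()
    calls = []
    region_ids = results["region_id"].unique()
    for condition, needed in conditions.items():
        for rid in region_ids:
            try:
                rows = [by_region.loc[(rid, c)] for c in needed]
            except KeyError:
                continue
            if any(isinstance(r, pd.DataFrame) for r in rows):
                raise ValueError(f"duplicate (region, contrast) rows for {rid}")
            if not all(_passes(r, fdr_threshold, fc) for r in rows):
                continue
            signs = {np.sign(r["estimate"]) for r in rows}
            if len(signs) != 1 or 0.0 in signs:
                continue
            status = "induced" if signs.pop() > 0 else "repressed"
            calls.append(
                {"region_id": rid, "condition": condition, "status": status}
            )
    return pd.DataFrame(calls, columns=["region_id", "condition", "status"])


def overexpression_conditions(
    contrasts: Sequence[ContrastSpec],
) -> dict[str, list[str]]:
    """Group over-expression contrasts into per-(genotype, sex) conditions."""
    out: dict[str, list[str]] = {}
    for c in contrasts:
        if c.family != FAMILY_OVEREXPRESSION:
            continue
        genotype, sex = c.group_a.split(":")
        out.setdefault(condition_label(genotype, sex), []).append(c.name)
    return {k: v for k, v in out.items() if len(v) == 2}


def null_condition(contrasts: Sequence[ContrastSpec]) -> dict[str, list[str]]:
    """The single four-comparison loss-of-function condition, if complete."""
    names = [c.name for c in contrasts if c.family == FAMILY_NULL]
    return {"fru_null:male": names} if len(names) == 4 else {}


def rollup_to_genes(
    calls: pd.DataFrame,
    region_to_gene: Mapping[str, str],
) -> pd.DataFrame:
    """Lift region-level calls to genes.

    A gene is induced (repressed) for a condition iff >= 1 of its regions
    carries that call; a gene carrying both calls via different regions keeps
    both rows and is flagged ``ambivalent``.
    """
    if calls.empty:
        return pd.DataFrame(columns=["gene_id", "condition", "status", "ambivalent"])
    rows = calls.assign(gene_id=calls["region_id"].map(region_to_gene)).dropna(
        subset=["gene_id"]
    )
    gene_level = (
        rows[["gene_id", "condition", "status"]].drop_duplicates().reset_index(drop=True)
    )
    both = gene_level.groupby(["gene_id", "condition"])["status"].transform("nunique")
    gene_level["ambivalent"] = both > 1
    return gene_level


def gene_sets(gene_calls: pd.DataFrame) -> dict[tuple[str, str], set[str]]:
    """(condition, status) -> set of gene ids."""
    out: dict[tuple[str, str], set[str]] = {}
    for row in gene_calls.itertuples(index=False):
        out.setdefault((row.condition, row.status), set()).add(row.gene_id)
    return out
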