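"""Per-region linear model, pooled BH correction, and compound call gating."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fruseq import diffexpr as de


def bh_oracle(pvals):
    """Definitional Benjamini-Hochberg step-up: adj_i = min_{j>=i} p_(j)*m/j."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def _series(groups):
    values, labels = {}, {}
    for cell, vals in groups.items():
        for k, v in enumerate(vals):
            sid = f"{cell}_{k}"
            values[sid] = v
            labels[sid] = cell
    return pd.Series(values, dtype=float), pd.Series(labels)


CONTRAST = de.ContrastSpec("a_vs_b", "a", "b", de.FAMILY_OVEREXPRESSION)


class TestFitRegionModel:
    def test_identical_groups_give_zero_estimate_p_one(self):
        y, cells = _series({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        (rec,) = de.fit_region_model(y, cells, [CONTRAST])
        assert rec["estimate"] == 0.0
        assert rec["raw_p"] == 1.0

    def test_matches_pooled_variance_t_oracle(self):
        a, b = [1.0, 1.1, 0.9], [2.0, 2.1, 1.9]
        y, cells = _series({"a": a, "b": b})
        (rec,) = de.fit_region_model(y, cells, [CONTRAST])
        assert rec["estimate"] == pytest.approx(-1.0, abs=1e-12)
        # closed-form two-sample pooled-variance t
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t = -1.0 / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        p = 2 * stats.t.sf(abs(t), 4)
        assert rec["raw_p"] == pytest.approx(p, rel=1e-12)
        assert rec["fold_change"] == pytest.approx(math.exp(-1.0))

    def test_third_cell_contributes_to_pooled_variance(self):
        y, cells = _series(
            {"a": [1.0, 1.2], "b": [2.0, 2.2], "c": [5.0, 9.0]}
        )
        (rec,) = de.fit_region_model(y, cells, [CONTRAST])
        sse = 0.02 * 2 + 8.0  # within-cell squared deviations
        s2 = sse / 3
        t = -1.0 / math.sqrt(s2 * (1 / 2 + 1 / 2))
        assert rec["raw_p"] == pytest.approx(2 * stats.t.sf(abs(t), 3), rel=1e-12)

    def test_all_missing_group_is_skipped_with_reason(self):
        y, cells = _series({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        (rec,) = de.fit_region_model(y, cells, [CONTRAST])
        assert np.isnan(rec["raw_p"])
        assert rec["reason"] == "all-missing group"

    def test_zero_residual_df_marked_untestable(self):
        y, cells = _series({"a": [1.0], "b": [2.0]})
        (rec,) = de.fit_region_model(y, cells, [CONTRAST])
        assert rec["reason"] == "zero residual df"

    def test_planted_effect_detected_in_simulation(self):
        rng = np.random.default_rng(7)
        n_sig = 0
        for _ in range(200):
            y, cells = _series(
                {
                    "a": list(rng.normal(math.log(4), 0.1, 3)),
                    "b": list(rng.normal(0.0, 0.1, 3)),
                }
            )
            (rec,) = de.fit_region_model(y, cells, [CONTRAST])
            n_sig += rec["raw_p"] < 0.05
        assert n_sig >= 190


class TestFdrCorrect:
    def _frame(self, pvals):
        return pd.DataFrame(
            {
                "region_id": [f"R{i}" for i in range(len(pvals))],
                "contrast": "c",
                "family": de.FAMILY_OVEREXPRESSION,
                "estimate": 1.0,
                "fold_change": math.e,
                "raw_p": pvals,
                "reason": "",
            }
        )

    def test_single_p_unchanged(self):
        out = de.fdr_correct(self._frame([0.04]))
        assert out["fdr_p"].iloc[0] == pytest.approx(0.04)

    def test_textbook_example(self):
        out = de.fdr_correct(self._frame([0.01, 0.02, 0.03, 0.04]))
        assert out["fdr_p"].tolist() == pytest.approx([0.04] * 4)

    def test_equal_ps_stay_equal(self):
        out = de.fdr_correct(self._frame([0.3] * 7))
        assert out["fdr_p"].nunique() == 1

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 400))
            out = de.fdr_correct(self._frame(p))
            assert np.allclose(out["fdr_p"].values, bh_oracle(p), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        out = de.fdr_correct(self._frame(p))
        assert (out["fdr_p"] >= out["raw_p"] - 1e-15).all()


def results_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["region_id", "contrast", "family", "estimate", "fold_change",
                 "raw_p", "fdr_p", "reason"],
    )


OE = de.FAMILY_OVEREXPRESSION
CONDITIONS = {"FruMA_OE:male": ["vs_CS", "vs_Berlin"]}


class TestCallDifferential:
    def test_single_background_significance_is_not_enough(self):
        res = results_frame(
            [
                ("R1", "vs_CS", OE, math.log(3), 3.0, 1e-4, 1e-3, ""),
                ("R1", "vs_Berlin", OE, math.log(1.1), 1.1, 0.5, 0.6, ""),
            ]
        )
        calls = de.call_differential(res, CONDITIONS, OE)
        assert calls.empty

    def test_both_backgrounds_significant_gives_induced(self):
        res = results_frame(
            [
                ("R1", "vs_CS", OE, math.log(2.5), 2.5, 1e-4, 1e-3, ""),
                ("R1", "vs_Berlin", OE, math.log(2.5), 2.5, 1e-4, 1e-3, ""),
            ]
        )
        calls = de.call_differential(res, CONDITIONS, OE)
        assert calls.status.tolist() == ["induced"]

    def test_fold_gate_respects_threshold(self):
        res = results_frame(
            [
                ("R1", "vs_CS", OE, math.log(1.5), 1.5, 1e-4, 1e-3, ""),
                ("R1", "vs_Berlin", OE, math.log(1.5), 1.5, 1e-4, 1e-3, ""),
            ]
        )
        assert de.call_differential(res, CONDITIONS, OE, fc_threshold=2.0).empty
        low = de.call_differential(res, CONDITIONS, OE, fc_threshold=1.4)
        assert len(low) == 1

    def test_direction_must_agree(self):
        res = results_frame(
            [
                ("R1", "vs_CS", OE, math.log(3), 3.0, 1e-4, 1e-3, ""),
                ("R1", "vs_Berlin", OE, -math.log(3), 1 / 3, 1e-4, 1e-3, ""),
            ]
        )
        assert de.call_differential(res, CONDITIONS, OE).empty

    def test_null_family_needs_all_four_but_no_fold_gate(self):
        needed = ["n1_vs_CS", "n1_vs_Berlin", "n2_vs_CS", "n2_vs_Berlin"]
        rows = [
            ("R1", c, de.FAMILY_NULL, math.log(1.3), 1.3, 1e-4, 1e-3, "")
            for c in needed
        ]
        calls = de.call_differential(
            results_frame(rows), {"fru_null:male": needed}, de.FAMILY_NULL
        )
        assert calls.status.tolist() == ["induced"]  # 1.3-fold passes: no gate
        rows[3] = ("R1", needed[3], de.FAMILY_NULL, math.log(1.3), 1.3, 0.5, 0.6, "")
        assert de.call_differential(
            results_frame(rows), {"fru_null:male": needed}, de.FAMILY_NULL
        ).empty

    def test_relaxing_thresholds_never_shrinks_call_sets(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(60):
            for c in ("vs_CS", "vs_Berlin"):
                est = rng.normal(0, 1.2)
                p = rng.uniform(0, 0.4)
                rows.append((f"R{i}", c, OE, est, math.exp(est), p, p, ""))
        res = results_frame(rows)
        strict = de.call_differential(res, CONDITIONS, OE, 0.10, 2.5)
        loose_fdr = de.call_differential(res, CONDITIONS, OE, 0.30, 2.5)
        loose_fc = de.call_differential(res, CONDITIONS, OE, 0.10, 1.5)
        key = lambda df: set(map(tuple, df.values))
        assert key(strict) <= key(loose_fdr)
        assert key(strict) <= key(loose_fc)


class TestRollup:
    def test_gene_called_from_one_of_many_regions(self):
        calls = pd.DataFrame(
            {"region_id": ["R1"], "condition": ["c"], "status": ["induced"]}
        )
        r2g = {f"R{i}": "g1" for i in range(1, 6)}
        out = de.rollup_to_genes(calls, r2g)
        assert out.gene_id.tolist() == ["g1"]
        assert not out.ambivalent.any()

    def test_opposite_regions_flag_gene_ambivalent(self):
        calls = pd.DataFrame(
            {
                "region_id": ["R1", "R2"],
                "condition": ["c", "c"],
                "status": ["induced", "repressed"],
            }
        )
        out = de.rollup_to_genes(calls, {"R1": "g1", "R2": "g1"})
        assert set(out.status) == {"induced", "repressed"}
        assert out.ambivalent.all()
        sets = de.gene_sets(out)
        assert sets[("c", "induced")] == {"g1"} and sets[("c", "repressed")] == {"g1"}

    def test_empty_calls_give_empty_sets(self):
        out = de.rollup_to_genes(pd.DataFrame(columns=["region_id", "condition", "status"]), {})
        assert out.empty and de.gene_sets(out) == {}
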