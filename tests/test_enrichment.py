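"""Contingency-table statistics, arm enrichment, and motif co-occurrence.

The worked example throughout is the published male Fru^A row: universe
14,903 genes, 752 induced, 9,382 motif-positive, 644 observed in both.
"""

from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest

from fruseq import enrichment as en


TABLE_A_MALE_INDUCED = np.array([[644, 108], [8738, 5413]])


class TestContingencyFromSets:
    def test_published_fru_a_male_induced_row(self):
        universe = 14903
        induced = {f"g{i}" for i in range(752)}
        motif_pos = {f"g{i}" for i in range(644)} | {
            f"m{i}" for i in range(9382 - 644)
        }
        table = en.contingency_from_sets(induced, motif_pos, universe)
        assert np.array_equal(table, TABLE_A_MALE_INDUCED)
        res = en.analyze_table(table)
        assert res.expected[0, 0] == pytest.approx(473.4123331, abs=1e-6)

    def test_set_equal_to_universe_gives_zero_chi2(self):
        members = {f"g{i}" for i in range(50)}
        prop = {f"g{i}" for i in range(20)}
        table = en.contingency_from_sets(members, prop, 50)
        assert table[0, 0] == 20 and table[1].sum() == 0
        # second row empty -> chi-square undefined, Fisher still fine
        with pytest.raises(ValueError):
            en.chisq_test(table)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            en.enrichment_test(
                en.GeneSet("s", frozenset(), 100),
                en.GeneSet("p", frozenset({"a"}), 100),
            )

    def test_inconsistent_inputs_raise(self):
        with pytest.raises(ValueError, match="negative"):
            en.contingency_from_sets({"a", "b"}, {"c"}, 2)  # d would be -1


class TestChiSquare:
    def test_published_value(self):
        chi2, df, p = en.chisq_test(TABLE_A_MALE_INDUCED)
        assert chi2 == pytest.approx(174.7423677, rel=1e-7)
        assert df == 1

    def test_proportional_table_gives_zero(self):
        chi2, _, p = en.chisq_test(np.array([[10, 90], [100, 900]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_identity_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = rng.integers(1, 500, size=4)
            chi2, _, _ = en.chisq_test(np.array([[a, b], [c, d]]))
            n = a + b + c + d
            closed = (
                n * (a * d - b * c) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            assert chi2 == pytest.approx(closed, rel=1e-9)

    def test_no_continuity_correction(self):
        # Yates-corrected value for this table is ~0.53; uncorrected ~0.66
        chi2, _, _ = en.chisq_test(np.array([[134, 70], [9248, 5451]]))
        assert chi2 == pytest.approx(0.66217505, rel=1e-6)


def fisher_oracle(table):
    """Exhaustive margin-fixed enumeration, point-probability two-tail."""
    (a, b), (c, d) = table
    r, k, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r + k - n), min(r, k)
    masses = {
        x: comb(r, x) * comb(n - r, k - x) / comb(n, k) for x in range(lo, hi + 1)
    }
    return sum(m for m in masses.values() if m <= masses[a] * (1 + 1e-9))


class TestFisher:
    def test_balanced_table_p_one(self):
        p, odds = en.fisher_exact_test(np.array([[5, 5], [5, 5]]))
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        table = np.array([[3, 1], [1, 3]])
        p, _ = en.fisher_exact_test(table)
        assert p == pytest.approx(fisher_oracle(table), rel=1e-12)

    def test_published_order_of_magnitude(self):
        p, _ = en.fisher_exact_test(TABLE_A_MALE_INDUCED)
        assert abs(np.log10(p) - np.log10(2.39e-45)) <= 1.0

    def test_transposition_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            t = rng.integers(0, 40, size=(2, 2))
            p1, _ = en.fisher_exact_test(t)
            p2, _ = en.fisher_exact_test(t.T)
            chi_ok = True
            if (en.expected_counts(t) > 0).all():
                c1, _, _ = en.chisq_test(t)
                c2, _, _ = en.chisq_test(t.T)
                chi_ok = c1 == pytest.approx(c2, rel=1e-12)
            assert p1 == pytest.approx(p2, rel=1e-9) and chi_ok


class TestRecoverPropertyTotal:
    def test_inverts_expected_count(self):
        m = en.recover_property_total(752, 473.4123331, 14903)
        assert m == pytest.approx(9382, abs=1e-3)

    def test_rejects_empty_set(self):
        with pytest.raises(ValueError):
            en.recover_property_total(0, 1.0, 10)


class TestChromosomeEnrichment:
    @staticmethod
    def _universe(n_per_arm=200):
        arms = ["X", "2L", "2R", "3L", "3R", "4"]
        return {
            f"g_{arm}_{i}": arm for arm in arms for i in range(n_per_arm)
        }

    def test_uniform_draws_rarely_flag_any_arm(self):
        gene_to_arm = self._universe()
        genes = sorted(gene_to_arm)
        rng = np.random.default_rng(0)
        clean = 0
        for _ in range(25):
            members = set(rng.choice(genes, size=120, replace=False))
            out = en.chromosome_enrichment(members, gene_to_arm)
            clean += not out.significant.any()
        assert clean >= 18  # ~six 5%-level tests per draw

    def test_all_x_set_is_enriched_on_x_depleted_elsewhere(self):
        gene_to_arm = self._universe()
        members = {g for g, a in gene_to_arm.items() if a == "X"}
        out = en.chromosome_enrichment(members, gene_to_arm).set_index("arm")
        assert out.loc["X", "significant"] and out.loc["X", "direction"] == "enriched"
        assert (out.drop("X").direction == "depleted").all()
        assert out.loc["X", "p_fisher"] == out.p_fisher.min()

    def test_planted_two_fold_x_bias_detected(self):
        gene_to_arm = self._universe()
        rng = np.random.default_rng(1)
        members = {
            g for g, a in gene_to_arm.items()
            if rng.random() < (0.4 if a == "X" else 0.2)
        }
        out = en.chromosome_enrichment(members, gene_to_arm).set_index("arm")
        assert out.loc["X", "significant"]
        assert out.loc["X", "direction"] == "enriched"

    def test_unmapped_genes_are_reported(self):
        gene_to_arm = {"a": "X", "b": "2L", "c": "2L", "d": "X"}
        out = en.chromosome_enrichment({"a", "zzz"}, gene_to_arm)
        assert out.attrs["n_unmapped"] == 1


class TestMotifCooccurrence:
    def test_independent_presence_odds_near_one(self):
        rng = np.random.default_rng(2)
        pres = pd.DataFrame(
            rng.random((3000, 3)) < 0.4, columns=["A", "B", "C"]
        )
        out = en.motif_cooccurrence(pres)
        assert np.median(np.abs(np.log(out.odds_ratio))) < 0.25

    def test_identical_presence_is_maximal_association(self):
        v = np.array([True] * 40 + [False] * 60)
        pres = pd.DataFrame({"A": v, "B": v})
        out = en.motif_cooccurrence(pres)
        assert out.odds_ratio.iloc[0] == np.inf
        assert out.p_fisher.iloc[0] < 1e-20

    def test_anticorrelated_presence_odds_below_one(self):
        v = np.array([True] * 50 + [False] * 50)
        pres = pd.DataFrame({"A": v, "B": ~v})
        out = en.motif_cooccurrence(pres)
        assert out.odds_ratio.iloc[0] < 1.0

    def test_single_motif_is_an_error(self):
        with pytest.raises(ValueError):
            en.motif_cooccurrence(pd.DataFrame({"A": [True, False]}))
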