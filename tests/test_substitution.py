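"""Substitution counting and the 50:50 asymmetry test machinery."""

import numpy as np
import pytest

from piezocomp import (
    DirectedSubstitutionMatrix,
    SimulationConfig,
    chi_square_asymmetry,
    count_substitutions,
    replacement_summary,
    simulate_ortholog_proteomes,
    test_all_pairs as all_pair_tests,
)
from piezocomp.align import AlignedPair
from piezocomp.alphabet import AA_INDEX, AA_ORDER
from piezocomp.orthology import OrthologSet, pair_alignments_from_truth


def _set(*pairs):
    out = OrthologSet()
    for k, (a, b) in enumerate(pairs):
        out.pairs.append(AlignedPair(f"a{k}", f"b{k}", a, b))
    return out


class TestCountSubstitutions:
    def test_single_pair_counts_by_definition(self):
        m = count_substitutions(_set(("ACD", "ACE")))
        assert m.count("A", "A") == 1
        assert m.count("C", "C") == 1
        assert m.count("D", "E") == 1
        assert m.total == 3

    def test_gap_columns_are_skipped(self):
        m = count_substitutions(_set(("A-CD", "AWCD")))
        assert m.total == 3
        assert np.all(m.counts == np.diag(np.diag(m.counts)))

    def test_ambiguity_columns_are_skipped(self):
        m = count_substitutions(_set(("AXCD", "AWCD")))
        assert m.total == 3

    def test_empty_set_gives_zero_matrix(self):
        m = count_substitutions(OrthologSet())
        assert m.total == 0

    def test_swapping_proteomes_transposes_the_matrix(self):
        pa, pb, truth = simulate_ortholog_proteomes(
            SimulationConfig(n_proteins=10, sub_rate=0.2, seed=8)
        )
        forward = count_substitutions(pair_alignments_from_truth(pa, pb, truth))
        swapped = OrthologSet()
        for p in pair_alignments_from_truth(pa, pb, truth).pairs:
            swapped.pairs.append(AlignedPair(p.id_b, p.id_a, p.aligned_b, p.aligned_a))
        backward = count_substitutions(swapped)
        assert np.array_equal(forward.counts.T, backward.counts)


class TestChiSquareAsymmetry:
    def test_perfect_symmetry_is_null(self):
        r = chi_square_asymmetry(100, 100)
        assert r.chi2 == 0.0 and r.p_value == 1.0 and not r.significant
        assert r.direction is None

    def test_zero_counts_is_undefined_and_not_significant(self):
        r = chi_square_asymmetry(0, 0)
        assert r.p_value == 1.0 and not r.significant

    def test_published_kr_counts_are_significant(self):
        """The K→R / R→K exchange (2689 vs 1969) is highly asymmetric."""
        r = chi_square_asymmetry(2689, 1969, a="K", b="R")
        assert r.chi2 == pytest.approx(111.29, abs=0.01)
        assert r.p_value < 1e-20
        assert r.significant and r.direction == "R"

    def test_published_ac_counts_are_not_significant(self):
        r = chi_square_asymmetry(374, 417, a="A", b="C")
        assert r.chi2 == pytest.approx(2.34, abs=0.01)
        assert r.p_value == pytest.approx(0.126, abs=0.01)
        assert not r.significant

    def test_swap_invariance_flips_direction_only(self):
        fwd = chi_square_asymmetry(120, 80, a="D", b="E")
        rev = chi_square_asymmetry(80, 120, a="D", b="E")
        assert fwd.chi2 == rev.chi2 and fwd.p_value == rev.p_value
        assert fwd.direction == "E" and rev.direction == "D"

    def test_exact_binomial_options(self):
        from scipy.stats import binomtest

        r = chi_square_asymmetry(60, 40, method="binomial")
        assert r.p_value == pytest.approx(binomtest(60, 100, 0.5).pvalue)
        r_mid = chi_square_asymmetry(60, 40, method="binomial-midp")
        assert 0 < r_mid.p_value < r.p_value  # mid-p is less conservative

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            chi_square_asymmetry(-1, 5)
        with pytest.raises(ValueError):
            chi_square_asymmetry(1, 5, alpha=0.0)
        with pytest.raises(ValueError):
            chi_square_asymmetry(1, 5, method="wald")


class TestTestAllPairs:
    def test_diagonal_only_matrix_yields_190_null_results(self):
        m = DirectedSubstitutionMatrix(np.diag(np.full(20, 100)))
        results = all_pair_tests(m)
        assert len(results) == 190
        assert all(r.p_value == 1.0 and not r.significant for r in results)

    def test_fixture_headline_pairs(self, table1):
        results = {frozenset((r.a, r.b)): r for r in all_pair_tests(table1)}
        assert results[frozenset("KR")].significant
        assert not results[frozenset("AC")].significant

    def test_results_sorted_by_p_value(self, table1):
        results = all_pair_tests(table1)
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)

    def test_exchange_conservation(self, table1):
        """Sum of x+y over all pairs equals the off-diagonal total."""
        results = all_pair_tests(table1)
        off_diag = table1.counts.sum() - np.trace(table1.counts)
        assert sum(r.x + r.y for r in results) == off_diag

    def test_chi2_agrees_with_exact_binomial_oracle(self, table1):
        """|p_chi2 - p_midp| <= 0.01 wherever x+y >= 30 in the fixture."""
        for r in all_pair_tests(table1):
            if r.x + r.y >= 30:
                exact = chi_square_asymmetry(r.x, r.y, method="binomial-midp")
                assert abs(r.p_value - exact.p_value) <= 0.01, (r.a, r.b)

    def test_bonferroni_correction_reduces_hits(self, table1):
        raw = sum(r.significant for r in all_pair_tests(table1, alpha=0.01))
        corrected = sum(
            r.significant
            for r in all_pair_tests(table1, alpha=0.01, correction="bonferroni")
        )
        assert corrected <= raw


class TestReplacementSummary:
    def test_diagonal_only_matrix_has_no_net_excess(self):
        m = DirectedSubstitutionMatrix(np.diag(np.full(20, 50)))
        summ = replacement_summary(m, all_pair_tests(m))
        assert (summ.table["net_excess"] == 0).all()
        assert summ.preferred_acceptors == []

    def test_toy_matrix_arithmetic(self):
        counts = np.diag(np.full(20, 100))
        counts[AA_INDEX["K"], AA_INDEX["R"]] = 10
        counts[AA_INDEX["R"], AA_INDEX["K"]] = 2
        m = DirectedSubstitutionMatrix(counts)
        results = all_pair_tests(m, alpha=0.05)
        summ = replacement_summary(m, results, min_pairs=1)
        assert summ.table.loc["K", "net_excess"] == 8
        assert summ.table.loc["K", "net_excess_pct"] == pytest.approx(
            100.0 * 8 / 110
        )
        assert summ.preferred_acceptors == ["R"]

    def test_fixture_headline_residues(self, table1):
        """E, K, N lose the most; A, H, R, T are among the main gainers."""
        results = all_pair_tests(table1)
        summ = replacement_summary(table1, results)
        top3 = set(summ.table.nlargest(3, "net_excess").index)
        assert top3 == {"E", "K", "N"}
        assert {"E", "K", "N", "S", "Y"} <= set(
            summ.table.index[summ.table["net_excess"] > 0]
        )
        assert {"A", "H", "R", "T"} <= set(summ.preferred_acceptors)


class TestMatrixType:
    def test_rejects_bad_shapes_and_negatives(self):
        with pytest.raises(ValueError):
            DirectedSubstitutionMatrix(np.zeros((19, 20)))
        bad = np.zeros((20, 20))
        bad[0, 1] = -1
        with pytest.raises(ValueError):
            DirectedSubstitutionMatrix(bad)

    def test_frame_round_trip(self, table1):
        again = DirectedSubstitutionMatrix.from_frame(table1.to_frame())
        assert np.array_equal(again.counts, table1.counts)

    def test_transpose_swaps_organisms(self, table1):
        t = table1.transpose()
        assert t.row_organism == table1.col_organism
        assert t.count("R", "K") == table1.count("K", "R")
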