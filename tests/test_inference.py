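"""McNemar, Cochran's Q, Bonferroni, letter groupings, kappa and power."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import cochrans_q as sm_cochrans_q
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from conftest import brute_force_cochran_q, brute_force_exact_mcnemar
from vbdg import (
    CorrectnessCube,
    bonferroni,
    cochran_q,
    fleiss_kappa,
    mcnemar,
    mcnemar_power,
    mcnemar_power_closed_form,
    mcnemar_sample_size,
    pairwise_groupings,
)
from vbdg.exceptions import ValidationError
from vbdg.inference import _insert_absorb


class TestMcNemar:
    def test_asymptotic_no_continuity(self):
        r = mcnemar(42, 8, mode="asymptotic")
        assert r.statistic == pytest.approx(34**2 / 50)
        assert r.df == 1
        assert r.p_value == pytest.approx(1.52e-6, rel=0.01)

    def test_continuity_correction(self):
        r = mcnemar(42, 8, mode="asymptotic", continuity=True)
        assert r.statistic == pytest.approx(33**2 / 50)

    def test_balanced_discordance_is_null(self):
        assert mcnemar(7, 7, mode="asymptotic").statistic == 0.0
        assert mcnemar(7, 7, mode="exact").p_value == 1.0

    def test_one_sided_extreme_exact(self):
        r = mcnemar(18, 0, mode="auto")
        assert r.method == "mcnemar_exact"
        assert r.p_value == pytest.approx(2 * 0.5**18)

    def test_no_discordance_degenerate(self):
        r = mcnemar(0, 0)
        assert r.p_value == 1.0
        assert "degenerate" in r.notes

    def test_auto_switches_at_cutoff(self):
        assert mcnemar(13, 12, mode="auto").method == "mcnemar_exact"
        assert mcnemar(13, 13, mode="auto").method == "mcnemar_asymptotic"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            mcnemar(-1, 3)

    def test_exact_matches_enumeration_exhaustively(self):
        for nd in range(1, 26):
            for b in range(nd + 1):
                c = nd - b
                assert mcnemar(b, c, mode="exact").p_value == pytest.approx(
                    brute_force_exact_mcnemar(b, c), abs=1e-12
                )

    @pytest.mark.parametrize("b, c", [(3, 9), (0, 7), (10, 10), (42, 8), (60, 41)])
    def test_cross_check_against_statsmodels(self, b, c):
        table = [[0, b], [c, 0]]
        exact = sm_mcnemar(table, exact=True)
        assert mcnemar(b, c, mode="exact").p_value == pytest.approx(
            float(exact.pvalue), abs=1e-9
        )
        asym = sm_mcnemar(table, exact=False, correction=False)
        assert mcnemar(b, c, mode="asymptotic").p_value == pytest.approx(
            float(asym.pvalue), abs=1e-9
        )


class TestCochranQ:
    def test_identical_columns_degenerate(self):
        x = np.tile(np.array([[1], [0], [1]]), (1, 4))
        r = cochran_q(x)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_toy_matrix_matches_brute_force(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, size=(6, 3))
        while len(np.unique(x.sum(axis=1))) == 1:
            x = rng.integers(0, 2, size=(6, 3))
        r = cochran_q(x)
        assert r.statistic == pytest.approx(brute_force_cochran_q(x))
        assert r.df == 2

    def test_k2_equals_mcnemar_chi2(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            x = rng.integers(0, 2, size=(rng.integers(4, 30), 2))
            b = int(((x[:, 0] == 1) & (x[:, 1] == 0)).sum())
            c = int(((x[:, 0] == 0) & (x[:, 1] == 1)).sum())
            q = cochran_q(x)
            if b + c == 0:
                assert q.p_value == 1.0
            else:
                m = mcnemar(b, c, mode="asymptotic")
                assert q.statistic == pytest.approx(m.statistic, abs=1e-10)

    def test_cross_check_against_statsmodels(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, size=(40, 4))
        r = cochran_q(x)
        sm = sm_cochrans_q(x)
        assert r.statistic == pytest.approx(float(sm.statistic))
        assert r.p_value == pytest.approx(float(sm.pvalue))

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            cochran_q(np.array([[0, 2], [1, 0]]))
        with pytest.raises(ValidationError):
            cochran_q(np.zeros((3, 1)))


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01], m=10)[0] == pytest.approx(0.10)
        assert bonferroni([0.5], m=10)[0] == 1.0
        assert bonferroni([0.2])[0] == pytest.approx(0.2)  # identity at m=1

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=8))
    def test_order_preserving(self, ps):
        adj = bonferroni(ps)
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_family_too_small(self):
        with pytest.raises(ValidationError):
            bonferroni([0.1, 0.2], m=1)


class TestLetterGroupings:
    def test_cld_three_group_chain(self):
        # A~B, B~C but A and C differ -> A:"a", B:"ab", C:"b"
        letters = _insert_absorb(["A", "B", "C"], {frozenset(("A", "C"))})
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_no_significant_pairs_single_letter(self):
        letters = _insert_absorb(["A", "B", "C"], set())
        assert set(letters.values()) == {"a"}

    def test_all_pairs_significant_distinct_letters(self):
        sig = {frozenset(p) for p in (("A", "B"), ("A", "C"), ("B", "C"))}
        letters = _insert_absorb(["A", "B", "C"], sig)
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_letters_reconstruct_significance_relation(self, ref_cohort):
        cube, _ = ref_cohort
        for k in cube.thresholds:
            g = pairwise_groupings(cube, k=k, alpha=0.05)
            for a in cube.condition_ids:
                for b in cube.condition_ids:
                    if a == b:
                        continue
                    shared = g.share_letter(a, b)
                    assert shared == (g.p_adjusted.loc[a, b] >= g.alpha)

    def test_reference_top1_letter_pattern(self, ref_cohort):
        cube, _ = ref_cohort
        g = pairwise_groupings(cube, k=1)
        assert g.letters["expert"] == "a"
        middle = {g.letters[c] for c in ("model_a_image", "model_b_image", "model_b_text")}
        assert middle == {"b"}
        assert g.letters["model_a_text"] == "c"


class TestFleissKappa:
    def test_perfect_agreement_is_exactly_one(self):
        ratings = [["low", "low", "low"], ["high", "high", "high"],
                   ["low", "low", "low"], ["moderate", "moderate", "moderate"]]
        assert fleiss_kappa(ratings) == 1.0

    def test_toy_matrix_matches_hand_formula(self):
        ratings = np.array(
            [["a", "a", "b"], ["b", "b", "b"], ["a", "b", "b"], ["a", "a", "a"]]
        )
        # hand computation of mean pairwise agreement and chance agreement
        counts = np.array([[2, 1], [0, 3], [1, 2], [3, 0]], dtype=float)
        n_r = 3
        p_bar = (((counts**2).sum(axis=1) - n_r) / (n_r * (n_r - 1))).mean()
        p_cat = counts.sum(axis=0) / counts.sum()
        p_e = (p_cat**2).sum()
        expected = (p_bar - p_e) / (1 - p_e)
        assert fleiss_kappa(ratings) == pytest.approx(expected)

    def test_rater_permutation_invariance(self):
        ratings = np.array(
            [["a", "b", "a"], ["b", "b", "a"], ["a", "a", "a"], ["b", "a", "b"]]
        )
        assert fleiss_kappa(ratings) == pytest.approx(
            fleiss_kappa(ratings[:, [2, 0, 1]])
        )

    def test_single_category_undefined(self):
        assert math.isnan(fleiss_kappa([["x", "x"], ["x", "x"]]))


class TestPower:
    def test_closed_form_sample_size_near_published_design(self):
        # 60% vs 80% under independence: p10 = 0.32, p01 = 0.12
        assert mcnemar_sample_size(0.32, 0.12, alpha=0.05, power=0.8) == 84

    def test_null_design_estimates_alpha(self):
        r = mcnemar_power(0.5, 0.5, 200, reps=4000, seed=3)
        assert "null" in r.notes
        assert abs(r.power - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / 4000)

    def test_power_non_decreasing_in_n(self):
        powers = [
            mcnemar_power(0.6, 0.8, n, reps=4000, seed=9).power
            for n in (40, 84, 150)
        ]
        tol = 3 * math.sqrt(0.25 / 4000)
        assert powers[1] >= powers[0] - tol
        assert powers[2] >= powers[1] - tol
        assert powers[2] > powers[0]

    def test_explicit_discordant_spec(self):
        r = mcnemar_power(0.6, 0.8, 84, discordant=(0.32, 0.12), reps=2000, seed=1)
        assert r.p10 == 0.32 and r.p01 == 0.12
        assert abs(r.power - r.closed_form) < 0.05

    def test_inconsistent_discordant_spec_rejected(self):
        with pytest.raises(ValidationError):
            mcnemar_power(0.6, 0.8, 84, discordant=(0.32, 0.30), reps=100, seed=1)

    def test_closed_form_null_returns_alpha(self):
        assert mcnemar_power_closed_form(0.0, 0.0, 80) == pytest.approx(0.05)
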