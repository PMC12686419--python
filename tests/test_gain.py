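"""VBDG metric algebra, Cohen's h and the between-model tests."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vbdg import (
    CorrectnessCube,
    PairedTable2x2,
    cohens_h,
    dod_bootstrap,
    dod_wald_test,
    rr_delta_test,
    vbdg_summary,
)
from vbdg.exceptions import ValidationError

proportions = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestVBDGSummary:
    @pytest.mark.parametrize(
        "a_img, a_text, abs_pp, rel, er",
        [
            (0.62, 0.45, 17.0, 1.38, 30.9),
            (0.80, 0.62, 18.0, 1.29, 47.4),
            (0.89, 0.72, 17.0, 1.24, 60.7),
            (0.64, 0.62, 2.0, 1.03, 5.3),
            (0.86, 0.87, -1.0, 0.99, -7.7),
        ],
    )
    def test_worked_examples(self, a_img, a_text, abs_pp, rel, er):
        r = vbdg_summary(a_img, a_text)
        assert round(r.absolute_gain_pp, 1) == abs_pp
        assert round(r.relative_gain, 2) == rel
        assert round(r.error_reduction_pct, 1) == er
        assert not r.undefined_flags

    def test_no_gain_is_identity(self):
        r = vbdg_summary(0.4, 0.4)
        assert r.absolute_gain_pp == 0.0
        assert r.relative_gain == 1.0
        assert r.error_reduction_pct == 0.0

    def test_zero_text_accuracy_flags_relative_gain(self):
        r = vbdg_summary(0.3, 0.0)
        assert math.isnan(r.relative_gain)
        assert r.undefined_flags == {"relative_gain"}

    def test_perfect_text_accuracy_flags_error_reduction(self):
        r = vbdg_summary(1.0, 1.0)
        assert math.isnan(r.error_reduction_pct)
        assert r.undefined_flags == {"error_reduction"}

    def test_table_overload_matches_marginals(self):
        t = PairedTable2x2(82, 42, 8, 68)
        r = vbdg_summary(table=t)
        assert r.a_img == pytest.approx(124 / 200)
        assert r.a_text == pytest.approx(90 / 200)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            vbdg_summary(1.2, 0.5)
        with pytest.raises(ValidationError):
            vbdg_summary(0.5, 0.5, table=PairedTable2x2(1, 1, 1, 1))

    @given(proportions, st.floats(min_value=1e-6, max_value=1.0))
    def test_abs_gain_identity(self, a_img, a_text):
        r = vbdg_summary(a_img, a_text)
        assert r.absolute_gain_pp == pytest.approx(
            100.0 * a_text * (r.relative_gain - 1.0), abs=1e-9
        )

    @given(proportions, st.floats(min_value=0.01, max_value=0.99))
    def test_sign_equivalence(self, a_img, a_text):
        r = vbdg_summary(a_img, a_text)
        assert (r.error_reduction_pct > 0) == (r.absolute_gain_pp > 0)
        assert (r.absolute_gain_pp > 0) == (r.relative_gain > 1)


class TestCohensH:
    def test_small_to_medium_worked_example(self):
        e = cohens_h(0.62, 0.45)
        assert round(e.cohens_h, 2) == 0.34
        assert e.magnitude == "small"

    def test_extremes_and_diagonal(self):
        assert cohens_h(1.0, 0.0).cohens_h == pytest.approx(math.pi)
        assert cohens_h(0.3, 0.3).cohens_h == 0.0
        assert cohens_h(0.3, 0.3).magnitude == "trivial"

    @pytest.mark.parametrize(
        "h_abs, label",
        [(0.1, "trivial"), (0.2, "small"), (0.49, "small"), (0.5, "medium"),
         (0.79, "medium"), (0.8, "large")],
    )
    def test_magnitude_benchmarks(self, h_abs, label):
        # invert h = 2 asin(sqrt(p)) - 0 to hit |h| exactly
        p = math.sin(h_abs / 2.0) ** 2
        assert cohens_h(p, 0.0).magnitude == label

    @given(proportions, proportions)
    def test_antisymmetric(self, p1, p2):
        assert cohens_h(p1, p2).cohens_h == pytest.approx(-cohens_h(p2, p1).cohens_h)

    @given(st.floats(min_value=0.05, max_value=0.2))
    def test_monotone_in_gap_for_fixed_midpoint(self, delta):
        mid = 0.5
        narrow = abs(cohens_h(mid + delta / 2, mid - delta / 2).cohens_h)
        wide = abs(cohens_h(mid + delta, mid - delta).cohens_h)
        assert wide > narrow


def _cube_from_columns(cols: dict[str, np.ndarray]) -> CorrectnessCube:
    names = tuple(cols)
    n = len(next(iter(cols.values())))
    values = np.stack([cols[c] for c in names], axis=1)[:, :, None]
    return CorrectnessCube(values, tuple(f"c{i}" for i in range(n)), names, (1,))


class TestDodWald:
    def test_identical_gains_degenerate(self):
        x = np.tile([1, 0], 10)
        cube = _cube_from_columns(
            {"a_img": x, "a_text": x, "b_img": x, "b_text": x}
        )
        r = dod_wald_test(cube, ("a_img", "a_text"), ("b_img", "b_text"), 1)
        assert r.statistic == 0.0 and r.p_value == 1.0
        assert "degenerate" in r.notes

    def test_derived_closed_form_on_zero_one_vector(self):
        # model 1 gains in exactly 10 of 100 cases; model 2 never
        n = 100
        a_text = np.zeros(n, dtype=int)
        a_img = np.zeros(n, dtype=int)
        a_img[:10] = 1
        flat = np.ones(n, dtype=int)
        cube = _cube_from_columns(
            {"a_img": a_img, "a_text": a_text, "b_img": flat, "b_text": flat}
        )
        r = dod_wald_test(cube, ("a_img", "a_text"), ("b_img", "b_text"), 1)
        d = (a_img - a_text).astype(float)  # independent enumeration of d
        expected_z = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        assert r.estimate == pytest.approx(10.0)
        assert r.statistic == pytest.approx(expected_z)

    def test_swap_flips_sign_keeps_p(self, ref_cohort):
        cube, _ = ref_cohort
        m1 = ("model_a_image", "model_a_text")
        m2 = ("model_b_image", "model_b_text")
        fwd = dod_wald_test(cube, m1, m2, 1)
        rev = dod_wald_test(cube, m2, m1, 1)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_permutation_invariance(self, ref_cohort):
        cube, _ = ref_cohort
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(list(cube.case_ids)))
        shuffled = cube.subset(perm)
        m1 = ("model_a_image", "model_a_text")
        m2 = ("model_b_image", "model_b_text")
        assert dod_wald_test(cube, m1, m2, 1).statistic == pytest.approx(
            dod_wald_test(shuffled, m1, m2, 1).statistic
        )

    def test_bootstrap_cross_check_agrees(self, ref_cohort):
        cube, _ = ref_cohort
        m1 = ("model_a_image", "model_a_text")
        m2 = ("model_b_image", "model_b_text")
        wald = dod_wald_test(cube, m1, m2, 1)
        boot = dod_bootstrap(cube, m1, m2, 1, reps=2000, seed=5)
        assert boot["estimate_pp"] == pytest.approx(wald.estimate)
        # bootstrap SE should be close to the analytic SE of the mean
        analytic_se = wald.estimate / wald.statistic
        assert boot["se_pp"] == pytest.approx(analytic_se, rel=0.15)


class TestRRDelta:
    def test_identical_tables_null(self):
        t = PairedTable2x2(30, 10, 5, 55)
        r = rr_delta_test(t, t)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_derived_variance_formula(self):
        t1 = PairedTable2x2(82, 42, 8, 68)
        t2 = PairedTable2x2(120, 5, 5, 70)
        r = rr_delta_test(t1, t2)
        v1 = 50 / (124 * 90)  # independent evaluation of the delta-method variance
        assert v1 == pytest.approx(0.004480, abs=5e-7)
        v2 = 10 / (125 * 125)
        expected = (math.log(124 / 90) - math.log(125 / 125)) / math.sqrt(v1 + v2)
        assert r.statistic == pytest.approx(expected)
        assert r.estimate == pytest.approx((124 / 90) / (125 / 125))

    def test_doubling_counts_halves_variance(self):
        t = PairedTable2x2(82, 42, 8, 68)
        t2 = PairedTable2x2(164, 84, 16, 136)
        null = PairedTable2x2(100, 10, 10, 80)
        z1 = rr_delta_test(t, null).statistic
        # doubling both tables multiplies each variance by 1/2 -> z * sqrt(2)
        null2 = PairedTable2x2(200, 20, 20, 160)
        z2 = rr_delta_test(t2, null2).statistic
        assert z2 == pytest.approx(z1 * math.sqrt(2))

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            rr_delta_test(PairedTable2x2(0, 0, 5, 5), PairedTable2x2(1, 1, 1, 1))
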