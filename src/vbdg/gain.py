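"""Vision-based diagnostic gain (VBDG) metrics and between-model tests.

The VBDG family quantifies the incremental diagnostic value of adding one
input modality (images) on top of another (text), for a model evaluated on
the same cases under both conditions:

* absolute gain  ``(A_img - A_text) * 100`` in percentage points,
* relative gain  ``A_img / A_text`` (dimensionless ratio),
* error reduction ``100 * (E_text - E_img) / E_text`` with ``E = 1 - A``,
  the fraction of the remaining text-only error removed by images.

The three are algebraically linked: ``abs_gain_pp = 100 * A_text *
(relative_gain - 1)`` whenever the ratio is defined.  Between-model
differences in gain are tested with a Wald test on the per-case
difference-of-differences (which respects within-case correlation across all
four conditions) and by comparing log risk ratios with a delta-method
variance.  Cohen's h supplies a standardized effect size for any pair of
proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CorrectnessCube
from .exceptions import ValidationError

__all__ = [
    "PairedTable2x2",
    "VBDGResult",
    "EffectSize",
    "TestResult",
    "vbdg_summary",
    "cohens_h",
    "dod_wald_test",
    "dod_bootstrap",
    "rr_delta_test",
]


@dataclass(frozen=True)
class PairedTable2x2:
    """Matched-pair 2x2 counts for one (image condition, text condition) pair.

    ``n10`` (symbol b) counts image-only-correct cases, ``n01`` (symbol c)
    text-only-correct cases; these discordant cells carry all the paired
    information used by McNemar tests and conditional odds ratios.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for name in ("n11", "n10", "n01", "n00"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n < 1:
            raise ValidationError("paired table must contain at least one case")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def b(self) -> int:
        """Image-only-correct (discordant) count."""
        return self.n10

    @property
    def c(self) -> int:
        """Text-only-correct (discordant) count."""
        return self.n01

    @property
    def a_img(self) -> float:
        return (self.n11 + self.n10) / self.n

    @property
    def a_text(self) -> float:
        return (self.n11 + self.n01) / self.n

    @classmethod
    def from_cube(
        cls, cube: CorrectnessCube, image_condition: str, text_condition: str, k: int
    ) -> "PairedTable2x2":
        return cls(*cube.paired_counts(image_condition, text_condition, k))


@dataclass(frozen=True)
class VBDGResult:
    """The three VBDG metrics for one model at one rank threshold.

    ``relative_gain`` is NaN (and flagged) when the text-only accuracy is 0;
    ``error_reduction_pct`` is NaN (and flagged) when the text-only accuracy
    is 1 (no remaining error to reduce).
    """

    a_text: float
    a_img: float
    absolute_gain_pp: float
    relative_gain: float
    error_reduction_pct: float
    undefined_flags: frozenset[str] = frozenset()

    def rendered(self) -> dict[str, float | None]:
        """Publication-style rounding: 1 dp for pp/%, 2 dp for the ratio."""
        return {
            "absolute_gain_pp": round(self.absolute_gain_pp, 1),
            "relative_gain": None
            if "relative_gain" in self.undefined_flags
            else round(self.relative_gain, 2),
            "error_reduction_pct": None
            if "error_reduction" in self.undefined_flags
            else round(self.error_reduction_pct, 1),
        }


@dataclass(frozen=True)
class EffectSize:
    """Cohen's h with its conventional magnitude label."""

    cohens_h: float
    magnitude: str


@dataclass(frozen=True)
class TestResult:
    """A hypothesis-test outcome: statistic, df (chi-square methods only), p."""

    statistic: float
    df: int | None
    p_value: float
    method: str
    notes: str = ""
    estimate: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and not math.isnan(self.p_value):
            raise ValidationError(f"p-value out of [0, 1]: {self.p_value}")


def _check_proportion(name: str, p: float) -> float:
    p = float(p)
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {p}")
    return p


def vbdg_summary(
    a_img: float | None = None,
    a_text: float | None = None,
    *,
    table: PairedTable2x2 | None = None,
) -> VBDGResult:
    """Compute the VBDG metric triple from two accuracies or a paired table.

    Parameters
    ----------
    a_img, a_text
        Accuracies in [0, 1] under the image and text conditions.
    table
        Alternatively, a :class:`PairedTable2x2`; its marginal accuracies
        are used.

    Examples
    --------
    >>> r = vbdg_summary(0.62, 0.45)
    >>> round(r.absolute_gain_pp, 1), round(r.relative_gain, 2)
    (17.0, 1.38)
    >>> round(r.error_reduction_pct, 1)
    30.9
    """
    if table is not None:
        if a_img is not None or a_text is not None:
            raise ValidationError("pass either accuracies or a table, not both")
        a_img, a_text = table.a_img, table.a_text
    if a_img is None or a_text is None:
        raise ValidationError("both a_img and a_text are required")
    a_img = _check_proportion("a_img", a_img)
    a_text = _check_proportion("a_text", a_text)

    flags: set[str] = set()
    abs_pp = (a_img - a_text) * 100.0
    if a_text == 0.0:
        rel = math.nan
        flags.add("relative_gain")
    else:
        rel = a_img / a_text
    if a_text == 1.0:
        er = math.nan
        flags.add("error_reduction")
    else:
        er = 100.0 * ((1.0 - a_text) - (1.0 - a_img)) / (1.0 - a_text)
    return VBDGResult(a_text, a_img, abs_pp, rel, er, frozenset(flags))


#: |h| cut points for the conventional magnitude labels.
_H_BENCHMARKS = ((0.2, "trivial"), (0.5, "small"), (0.8, "medium"))


def cohens_h(p1: float, p2: float) -> EffectSize:
    """Cohen's h effect size for two proportions.

    ``h = 2*arcsin(sqrt(p1)) - 2*arcsin(sqrt(p2))``, signed; the magnitude
    label applies the usual benchmarks to |h|
    (trivial < 0.2 <= small < 0.5 <= medium < 0.8 <= large).
    """
    p1 = _check_proportion("p1", p1)
    p2 = _check_proportion("p2", p2)
    h = 2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p2))
    mag = "large"
    for cut, label in _H_BENCHMARKS:
        if abs(h) < cut:
            mag = label
            break
    return EffectSize(h, mag)


def _per_case_gains(cube: CorrectnessCube, pair: tuple[str, str], k: int) -> np.ndarray:
    img, text = pair
    return cube.slice(img, k).astype(np.int8) - cube.slice(text, k).astype(np.int8)


def dod_wald_test(
    cube: CorrectnessCube,
    model1: tuple[str, str],
    model2: tuple[str, str],
    k: int,
) -> TestResult:
    """Wald test on the between-model difference of vision-based gains.

    Per case i, each model's gain is ``g_i = x_img,i - x_text,i`` in
    {-1, 0, +1}; the test statistic is the standardized mean of
    ``d_i = g1_i - g2_i`` using the per-case paired-difference standard
    deviation, which respects within-case correlation across all four
    conditions.  ``estimate`` reports the difference-of-differences in
    percentage points.

    Parameters
    ----------
    model1, model2
        ``(image_condition_id, text_condition_id)`` pairs.
    """
    d = (_per_case_gains(cube, model1, k) - _per_case_gains(cube, model2, k)).astype(float)
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if n > 1 else 0.0
    dod_pp = mean * 100.0
    if sd == 0.0:
        if mean == 0.0:
            return TestResult(0.0, None, 1.0, "dod_wald",
                              "degenerate: all per-case differences are zero", dod_pp)
        return TestResult(math.inf if mean > 0 else -math.inf, None, 0.0, "dod_wald",
                          "degenerate: zero variance with non-zero mean (infinite z)", dod_pp)
    z = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return TestResult(z, None, min(p, 1.0), "dod_wald", "", dod_pp)


def dod_bootstrap(
    cube: CorrectnessCube,
    model1: tuple[str, str],
    model2: tuple[str, str],
    k: int,
    reps: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Case-resampling bootstrap cross-check for :func:`dod_wald_test`.

    Resamples cases with replacement and returns the bootstrap standard
    error, a percentile CI for the difference-of-differences (pp), and a
    normal-approximation two-sided p-value based on the bootstrap SE.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    d = (_per_case_gains(cube, model1, k) - _per_case_gains(cube, model2, k)).astype(float)
    n = d.size
    idx = rng.integers(0, n, size=(reps, n))
    boots = d[idx].mean(axis=1) * 100.0
    est = float(d.mean()) * 100.0
    se = float(boots.std(ddof=1))
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    p = 1.0 if se == 0.0 and est == 0.0 else (
        0.0 if se == 0.0 else min(1.0, 2.0 * float(stats.norm.sf(abs(est) / se)))
    )
    return {"estimate_pp": est, "se_pp": se, "ci_low_pp": float(lo),
            "ci_high_pp": float(hi), "p_value": p}


def rr_delta_test(t1: PairedTable2x2, t2: PairedTable2x2) -> TestResult:
    """Compare two models' risk ratios (image vs text) on the log scale.

    Per model, ``RR = A_img / A_text`` with the matched-pair delta-method
    variance ``Var(ln RR) = (n10 + n01) / ((n11 + n10) * (n11 + n01))``;
    ``z = (ln RR1 - ln RR2) / sqrt(V1 + V2)``, two-sided normal p.  The two
    models' log risk ratios are treated as independent (the minimal
    assumption); :func:`dod_bootstrap` captures shared-case covariance if
    needed.  ``estimate`` reports ``RR1 / RR2``.
    """
    def _log_rr(t: PairedTable2x2) -> tuple[float, float]:
        img_total = t.n11 + t.n10
        text_total = t.n11 + t.n01
        if img_total == 0 or text_total == 0:
            raise ValidationError(
                "risk ratio undefined: a marginal correct count is zero"
            )
        var = (t.n10 + t.n01) / (img_total * text_total)
        return math.log(img_total / text_total), var

    l1, v1 = _log_rr(t1)
    l2, v2 = _log_rr(t2)
    ratio = math.exp(l1 - l2)
    if v1 + v2 == 0.0:
        if l1 == l2:
            return TestResult(0.0, None, 1.0, "rr_delta",
                              "degenerate: no discordant pairs in either table", ratio)
        return TestResult(math.inf if l1 > l2 else -math.inf, None, 0.0, "rr_delta",
                          "degenerate: zero variance with unequal log RRs", ratio)
    z = (l1 - l2) / math.sqrt(v1 + v2)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return TestResult(z, None, p, "rr_delta", "", ratio)
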