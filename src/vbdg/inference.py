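"""Matched-pair and matched-set inference.

McNemar's test (exact and asymptotic, with an automatic switch at small
discordant counts), Cochran's Q for k >= 2 matched binary conditions,
Bonferroni adjustment, Bonferroni-adjusted pairwise McNemar comparisons
summarized as a compact letter display, Fleiss' kappa for inter-rater
agreement on the stratum labels, and power / sample-size machinery for the
McNemar design.

Conventions (deliberate, and needed to reproduce standard reported values):

* the exact two-sided McNemar p is ``min(1, 2 * P(X >= max(b, c)))`` with
  ``X ~ Binomial(b + c, 1/2)`` — the doubled-one-tail convention, which for
  the symmetric Binomial(n, 1/2) coincides with the min-likelihood two-sided
  tail;
* the asymptotic statistic is ``(|b - c| - cc)^2 / (b + c)`` with the
  continuity correction OFF by default (so that Cochran's Q at k = 2 equals
  the McNemar chi-square exactly);
* ``mode="auto"`` uses the exact test iff ``b + c <= 25``.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats import inter_rater as _ir

from .cohort import CorrectnessCube
from .exceptions import ValidationError
from .gain import TestResult

__all__ = [
    "mcnemar",
    "cochran_q",
    "bonferroni",
    "CLDGrouping",
    "pairwise_groupings",
    "fleiss_kappa",
    "PowerResult",
    "mcnemar_power",
    "mcnemar_power_closed_form",
    "mcnemar_sample_size",
    "discordant_probabilities",
]

#: Discordant-count cutoff at or below which ``mode="auto"`` goes exact.
DEFAULT_EXACT_CUTOFF = 25


def _check_count(name: str, v) -> int:
    if not isinstance(v, (int, np.integer)) or v < 0:
        raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
    return int(v)


def mcnemar(
    b: int,
    c: int,
    mode: str = "auto",
    continuity: bool = False,
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
) -> TestResult:
    """McNemar's test of marginal homogeneity on the discordant counts.

    Parameters
    ----------
    b, c
        Discordant counts (correct under exactly one of the two paired
        conditions).
    mode
        ``"exact"``, ``"asymptotic"``, or ``"auto"`` (exact iff
        ``b + c <= exact_cutoff``).
    continuity
        Apply the Yates-style continuity correction to the asymptotic
        statistic.  Off by default.

    Notes
    -----
    ``b + c == 0`` carries no paired information: returns p = 1 with a
    degenerate note.
    """
    b = _check_count("b", b)
    c = _check_count("c", c)
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValidationError(f"unknown mode {mode!r}")
    nd = b + c
    if nd == 0:
        return TestResult(0.0, None, 1.0, "mcnemar_degenerate",
                          "degenerate: no discordant pairs")
    use_exact = mode == "exact" or (mode == "auto" and nd <= exact_cutoff)
    if use_exact:
        # two-sided doubled tail of Binomial(nd, 1/2)
        m = max(b, c)
        p = min(1.0, 2.0 * float(stats.binom.sf(m - 1, nd, 0.5)))
        return TestResult(float(m), None, p, "mcnemar_exact")
    cc = 1.0 if continuity else 0.0
    chi2 = (abs(b - c) - cc) ** 2 / nd
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult(chi2, 1, p, "mcnemar_asymptotic",
                      "continuity corrected" if continuity else "")


def cochran_q(matrix: np.ndarray) -> TestResult:
    """Cochran's Q test for k >= 2 matched binary conditions.

    ``Q = k(k-1) * sum_j (C_j - N/k)^2 / (k * sum_i R_i - sum_i R_i^2)``
    with column sums ``C_j``, row sums ``R_i`` and grand total ``N``;
    chi-square with ``k - 1`` df under the null of equal marginal
    proportions.  Rows with all-0 or all-1 responses contribute nothing to
    either numerator deviations' variance or the denominator beyond their
    fixed totals; if every row is constant the statistic is degenerate
    (Q = 0, p = 1, flagged).
    """
    x = np.asarray(matrix)
    if x.ndim != 2:
        raise ValidationError(f"matrix must be 2-d, got shape {x.shape}")
    if not np.isin(x, (0, 1)).all():
        raise ValidationError("matrix entries must be 0 or 1")
    n, k = x.shape
    if k < 2:
        raise ValidationError("need at least 2 conditions")
    x = x.astype(float)
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    grand = x.sum()
    denom = k * row.sum() - (row**2).sum()
    if denom == 0.0:
        return TestResult(0.0, k - 1, 1.0, "cochran_q",
                          "degenerate: every case responds identically across conditions")
    q = k * (k - 1) * ((col - grand / k) ** 2).sum() / denom
    p = float(stats.chi2.sf(q, df=k - 1))
    return TestResult(float(q), k - 1, p, "cochran_q")


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``p_adj = min(1, m * p)``, order preserving.

    ``m`` defaults to the number of p-values and must be at least that.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValidationError(f"family size m={m} smaller than number of p-values {p.size}")
    return np.minimum(1.0, m * p)


@dataclass(frozen=True)
class CLDGrouping:
    """Compact letter display over a set of conditions.

    ``letters`` maps each condition id to its letter string; two conditions
    share at least one letter iff their Bonferroni-adjusted pairwise McNemar
    p-value is >= alpha.  Letters are assigned in accuracy-descending order
    starting at "a".
    """

    letters: dict[str, str]
    p_adjusted: pd.DataFrame
    alpha: float

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def _insert_absorb(ordered: list[str], significant: set[frozenset]) -> dict[str, str]:
    """Piepho-style insert-and-absorb letter assignment.

    Starts from one class containing everything; for each significantly
    different pair, every class containing both is split into two classes
    omitting one member each; classes contained in another are absorbed.
    """
    classes: list[set[str]] = [set(ordered)]
    for pair in sorted(significant, key=lambda s: tuple(sorted(ordered.index(x) for x in s))):
        a, b = sorted(pair, key=ordered.index)
        new_classes: list[set[str]] = []
        for cls in classes:
            if a in cls and b in cls:
                new_classes.append(cls - {a})
                new_classes.append(cls - {b})
            else:
                new_classes.append(cls)
        # absorb: drop empty classes, proper subsets of another class, duplicates
        kept: list[set[str]] = []
        for cls in new_classes:
            if not cls:
                continue
            if any(cls < other for other in new_classes if other is not cls):
                continue
            if cls not in kept:
                kept.append(cls)
        classes = kept
    # order classes by the rank of their best (highest-accuracy) member
    classes.sort(key=lambda cls: min(ordered.index(x) for x in cls))
    letters = {cond: "" for cond in ordered}
    alphabet = string.ascii_lowercase
    for i, cls in enumerate(classes):
        letter = alphabet[i] if i < 26 else f"z{i}"
        for cond in cls:
            letters[cond] += letter
    return {cond: "".join(sorted(letters[cond])) for cond in ordered}


def pairwise_groupings(
    cube: CorrectnessCube,
    conditions: list[str] | None = None,
    k: int = 1,
    alpha: float = 0.05,
    m: int | None = None,
    mode: str = "auto",
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
) -> CLDGrouping:
    """All-pairs McNemar comparisons with Bonferroni letters.

    Runs the ``C(q, 2)`` pairwise McNemar tests (auto exact/asymptotic),
    Bonferroni-adjusts with family size ``m`` (default ``C(q, 2)``), and
    summarizes the significance relation as a compact letter display with
    conditions ordered by descending Top-k accuracy.
    """
    conds = list(conditions) if conditions is not None else list(cube.condition_ids)
    if len(conds) < 2:
        raise ValidationError("need at least 2 conditions for pairwise comparisons")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    ordered = sorted(conds, key=lambda cond: (-cube.accuracy(cond, k).proportion, conds.index(cond)))
    pairs = [(a, b) for i, a in enumerate(ordered) for b in ordered[i + 1:]]
    family = m if m is not None else len(pairs)
    raw = []
    for a, b in pairs:
        n11, n10, n01, n00 = cube.paired_counts(a, b, k)
        raw.append(mcnemar(n10, n01, mode=mode, exact_cutoff=exact_cutoff).p_value)
    adj = bonferroni(raw, m=family)
    p_mat = pd.DataFrame(np.ones((len(ordered), len(ordered))), index=ordered, columns=ordered)
    significant: set[frozenset] = set()
    for (a, b), p in zip(pairs, adj):
        p_mat.loc[a, b] = p_mat.loc[b, a] = p
        if p < alpha:
            significant.add(frozenset((a, b)))
    letters = _insert_absorb(ordered, significant)
    return CLDGrouping(letters, p_mat, alpha)


def fleiss_kappa(ratings) -> float:
    """Fleiss' kappa for complete categorical ratings (subjects x raters).

    Accepts a 2-d array of categorical labels (any hashable values), one row
    per subject and one column per rater.  Returns NaN when the chance
    agreement is 1 (a single category used everywhere), where kappa is
    undefined.
    """
    x = np.asarray(ratings, dtype=object)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("need >= 2 subjects and >= 2 raters")
    table, _cats = _ir.aggregate_raters(x)
    n_cat = table.shape[1]
    if n_cat < 2:
        return math.nan
    p_cat = table.sum(axis=0) / table.sum()
    p_e = float((p_cat**2).sum())
    if p_e >= 1.0:
        return math.nan
    kappa = float(_ir.fleiss_kappa(table, method="fleiss"))
    # exact 1.0 at perfect agreement despite floating-point noise
    n_raters = x.shape[1]
    p_bar = float(((table**2).sum(axis=1) - n_raters).mean() / (n_raters * (n_raters - 1)))
    if p_bar == 1.0:
        return 1.0
    return kappa


# ---------------------------------------------------------------------------
# power / sample size for the paired McNemar design
# ---------------------------------------------------------------------------


def discordant_probabilities(
    p_text: float, p_img: float, rho: float = 0.0
) -> tuple[float, float]:
    """Discordant-cell probabilities (p10, p01) under the latent-threshold model.

    The same Gaussian-copula model as :func:`vbdg.simulate.simulate_cohort`:
    two binary outcomes with marginals ``p_img`` and ``p_text`` and latent
    normal correlation ``rho`` (``rho = 0`` gives independence).
    """
    for name, p in (("p_text", p_text), ("p_img", p_img)):
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1], got {p}")
    if not (0.0 <= rho < 1.0):
        raise ValidationError(f"rho must lie in [0, 1), got {rho}")
    if rho == 0.0:
        p11 = p_img * p_text
    else:
        a = stats.norm.ppf(p_img)
        b = stats.norm.ppf(p_text)
        if np.isinf(a) or np.isinf(b):
            p11 = min(p_img, p_text)
        else:
            cov = [[1.0, rho], [rho, 1.0]]
            p11 = float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([a, b]))
    p10 = p_img - p11   # image correct, text wrong
    p01 = p_text - p11  # text correct, image wrong
    return max(p10, 0.0), max(p01, 0.0)


def mcnemar_power_closed_form(
    p10: float, p01: float, n: int, alpha: float = 0.05
) -> float:
    """Connor-style normal approximation to the power of McNemar's test.

    With ``psi = p10 + p01`` and ``delta = p10 - p01``,
    ``power = Phi((|delta| sqrt(n) - z_{1-alpha/2} sqrt(psi)) /
    sqrt(psi - delta^2))``.
    """
    psi = p10 + p01
    delta = p10 - p01
    if psi <= 0:
        return float(alpha) if delta == 0 else 1.0
    z_a = float(stats.norm.ppf(1 - alpha / 2))
    denom = math.sqrt(max(psi - delta**2, 1e-12))
    arg = (abs(delta) * math.sqrt(n) - z_a * math.sqrt(psi)) / denom
    return float(stats.norm.cdf(arg))


def mcnemar_sample_size(
    p10: float, p01: float, alpha: float = 0.05, power: float = 0.8
) -> int:
    """Smallest n at which the closed-form McNemar power reaches ``power``."""
    psi = p10 + p01
    delta = p10 - p01
    if delta == 0:
        raise ValidationError("no effect: p10 == p01, sample size undefined")
    z_a = float(stats.norm.ppf(1 - alpha / 2))
    z_b = float(stats.norm.ppf(power))
    n = (z_a * math.sqrt(psi) + z_b * math.sqrt(psi - delta**2)) ** 2 / delta**2
    return int(math.ceil(n))


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo power estimate with its closed-form reference."""

    power: float
    mc_se: float
    closed_form: float
    p10: float
    p01: float
    n: int
    reps: int
    alpha: float
    notes: str = ""


def mcnemar_power(
    p_text: float,
    p_img: float,
    n: int,
    alpha: float = 0.05,
    rho: float = 0.0,
    discordant: tuple[float, float] | None = None,
    reps: int = 2000,
    seed: int | None = None,
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
) -> PowerResult:
    """Monte-Carlo power of the auto-mode McNemar test for a paired design.

    Per-case joint correctness follows the latent-threshold model with
    dependence ``rho`` (or, when ``discordant=(p10, p01)`` is given, exactly
    those discordant probabilities).  Each replicate draws the four paired
    cells from a multinomial and applies :func:`mcnemar` in auto mode.

    Returns the empirical rejection rate, its Monte-Carlo standard error and
    the closed-form approximation for reference.  Under the null
    (``p_img == p_text``) the estimate is the attained type-I error and the
    result is flagged.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if discordant is not None:
        p10, p01 = (float(discordant[0]), float(discordant[1]))
        p11 = p_img - p10
        if p11 < -1e-9 or abs((p11 + p01) - p_text) > 1e-9:
            raise ValidationError(
                "discordant probabilities inconsistent with the marginal accuracies"
            )
        p11 = max(p11, 0.0)
    else:
        p10, p01 = discordant_probabilities(p_text, p_img, rho)
        p11 = p_img - p10
    p00 = 1.0 - p11 - p10 - p01
    probs = np.clip([p11, p10, p01, p00], 0.0, 1.0)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    cells = rng.multinomial(n, probs, size=reps)
    b, c = cells[:, 1], cells[:, 2]
    p_vals = _mcnemar_p_vector(b, c, exact_cutoff)
    rejections = p_vals < alpha
    power = float(rejections.mean())
    mc_se = float(math.sqrt(power * (1 - power) / reps))
    closed = mcnemar_power_closed_form(p10, p01, n, alpha)
    notes = "null design: estimate is the attained type-I error" if p_img == p_text else ""
    return PowerResult(power, mc_se, closed, p10, p01, n, reps, alpha, notes)


def _mcnemar_p_vector(b: np.ndarray, c: np.ndarray, exact_cutoff: int) -> np.ndarray:
    """Vectorized auto-mode McNemar p-values for arrays of discordant counts."""
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    nd = b + c
    p = np.ones(b.shape, dtype=float)
    exact = (nd > 0) & (nd <= exact_cutoff)
    if exact.any():
        m = np.maximum(b[exact], c[exact])
        p[exact] = np.minimum(1.0, 2.0 * stats.binom.sf(m - 1, nd[exact], 0.5))
    asym = nd > exact_cutoff
    if asym.any():
        chi2 = (np.abs(b[asym] - c[asym])) ** 2 / nd[asym]
        p[asym] = stats.chi2.sf(chi2, df=1)
    return p
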