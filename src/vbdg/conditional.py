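"""Within-case (discordant-pair) odds ratios for the incremental image effect.

For a matched binary pair the conditional-logistic odds ratio of the
within-case exposure (images present vs absent) reduces to ``b / c`` on the
discordant cells, with log-scale Wald variance ``1/b + 1/c``.  When one
discordant cell is zero the Haldane–Anscombe correction adds 0.5 to *both*
discordant cells so the estimate and its interval stay finite; p-values come
from McNemar's test on the *uncorrected* counts (the correction serves
estimation, not testing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .exceptions import NoDiscordanceError, ReconstructionError, ValidationError
from .gain import PairedTable2x2, TestResult
from .inference import DEFAULT_EXACT_CUTOFF, mcnemar

__all__ = ["ORResult", "conditional_or", "reconstruct_paired_table"]


@dataclass(frozen=True)
class ORResult:
    """Discordant-pair odds ratio with Wald CI and McNemar p-value."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    alpha: float
    corrected: bool
    p_value: float
    b_used: float
    c_used: float

    def rendered(self) -> dict[str, float]:
        """Two-decimal rendering as used in clinical tables."""
        return {
            "odds_ratio": round(self.odds_ratio, 2),
            "ci_low": round(self.ci_low, 2),
            "ci_high": round(self.ci_high, 2),
        }


def _critical_z(alpha: float, exact_z: bool) -> float:
    z = float(stats.norm.ppf(1 - alpha / 2))
    # Clinical tables conventionally use the two-decimal critical value
    # (1.96 at alpha = 0.05); keep that as the reporting default.
    return z if exact_z else round(z, 2)


def conditional_or(
    table: PairedTable2x2,
    alpha: float = 0.05,
    exact_z: bool = False,
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
) -> ORResult:
    """Within-case odds ratio (image vs text) from a matched-pair table.

    ``OR = b / c`` on the discordant cells.  If either discordant cell is
    zero, 0.5 is added to both (Haldane–Anscombe; ``corrected`` flag set).
    The Wald interval is ``exp(ln OR +/- z * sqrt(1/b_used + 1/c_used))``;
    the p-value is McNemar's test (auto exact/asymptotic) on the
    uncorrected counts.

    Parameters
    ----------
    exact_z
        Use the full-precision normal quantile instead of the conventional
        two-decimal critical value.

    Raises
    ------
    NoDiscordanceError
        Both discordant cells are zero.

    Examples
    --------
    >>> r = conditional_or(PairedTable2x2(82, 42, 8, 68))
    >>> r.rendered()
    {'odds_ratio': 5.25, 'ci_low': 2.46, 'ci_high': 11.18}
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    b, c = table.b, table.c
    if b + c == 0:
        raise NoDiscordanceError(
            "no discordant pairs: the within-case odds ratio is undefined"
        )
    corrected = b == 0 or c == 0
    b_used = b + 0.5 if corrected else float(b)
    c_used = c + 0.5 if corrected else float(c)
    or_hat = b_used / c_used
    se = math.sqrt(1.0 / b_used + 1.0 / c_used)
    z = _critical_z(alpha, exact_z)
    ci_low = math.exp(math.log(or_hat) - z * se)
    ci_high = math.exp(math.log(or_hat) + z * se)
    p = mcnemar(b, c, mode="auto", exact_cutoff=exact_cutoff).p_value
    return ORResult(or_hat, ci_low, ci_high, alpha, corrected, p, b_used, c_used)


def reconstruct_paired_table(
    n: int,
    a_text: float,
    a_img: float,
    or_target: float,
    tolerance: float = 1e-6,
) -> PairedTable2x2:
    """Recover the unique integer paired table from printed marginals.

    Solves ``b - c = n * (a_img - a_text)`` together with ``b / c =
    or_target`` (or, when the solution forces ``c = 0``, the
    Haldane–Anscombe-corrected ``(b + 0.5) / 0.5 = or_target``), then fills
    ``n11 = n * a_text - c`` and ``n00 = n - n11 - b - c``.  Intended for
    rebuilding worked-example fixtures from published accuracy/OR pairs.

    Raises
    ------
    ReconstructionError
        If no non-negative integer table satisfies the constraints within
        ``tolerance`` (with diagnostics naming the failing constraint).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if or_target <= 0:
        raise ValidationError(f"or_target must be positive, got {or_target}")
    text_count = n * a_text
    img_count = n * a_img
    if abs(text_count - round(text_count)) > max(tolerance * n, 0.5 * 1e-3):
        raise ReconstructionError(
            f"n * a_text = {text_count} is not an integer within tolerance"
        )
    if abs(img_count - round(img_count)) > max(tolerance * n, 0.5 * 1e-3):
        raise ReconstructionError(
            f"n * a_img = {img_count} is not an integer within tolerance"
        )
    text_count = int(round(text_count))
    img_count = int(round(img_count))
    diff = img_count - text_count  # = b - c

    candidates: list[tuple[int, int]] = []
    if abs(or_target - 1.0) > tolerance:
        c_real = diff / (or_target - 1.0)
        c_int = round(c_real)
        if c_int >= 1 and abs(c_real - c_int) <= max(tolerance * max(abs(c_real), 1.0), 1e-9):
            candidates.append((diff + c_int, c_int))
    else:
        if diff == 0:
            raise ReconstructionError(
                "OR = 1 with equal accuracies leaves b = c unidentified; "
                "no unique table exists"
            )
    # Haldane–Anscombe variant: c = 0, target = (b + 0.5) / 0.5
    b_ha = 0.5 * or_target - 0.5
    if abs(b_ha - round(b_ha)) <= tolerance and round(b_ha) == diff and diff >= 1:
        candidates.append((diff, 0))
    # symmetric variant: b = 0, target = 0.5 / (c + 0.5)
    if or_target < 1.0:
        c_ha = 0.5 / or_target - 0.5
        if abs(c_ha - round(c_ha)) <= 1e-6 and round(c_ha) == -diff and diff <= -1:
            candidates.append((0, -diff))

    for b, c in candidates:
        n11 = text_count - c
        n00 = n - n11 - b - c
        if b < 0 or c < 0 or n11 < 0 or n00 < 0:
            continue
        table = PairedTable2x2(n11, b, c, n00)
        return table
    raise ReconstructionError(
        f"no integer table with n={n}, a_text={a_text}, a_img={a_img} "
        f"reproduces OR {or_target} (needed b - c = {diff})"
    )
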