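"""Correlated-binary cohort simulation and the packaged worked-example cohort.

The generator produces per-case binary correctness for several conditions
with specified marginal Top-k accuracies and exchangeable within-case
dependence, using a latent-threshold Gaussian copula: each case draws a
shared standard-normal ``z_i``; condition c draws
``t_ic = sqrt(rho) * z_i + sqrt(1 - rho) * eps_ic`` and is correct at
threshold k iff ``t_ic < Phi^{-1}(p_ck)``.  Marginals are exact in
expectation; a single ``rho`` controls the within-case dependence across any
number of conditions; sharing ``t_ic`` across thresholds gives the monotone
coupling that keeps every generated cube threshold-monotone.

:func:`reference_cohort` packages a deterministic 200-case, 5-condition
cohort whose margins reproduce the published worked example used throughout
the tests and README (see docs/methods.md for exactly which joint cells are
constrained and which follow a documented canonical arrangement).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DEFAULT_THRESHOLDS, CorrectnessCube
from .exceptions import SimulationSpecError, ValidationError
from .inference import _mcnemar_p_vector, discordant_probabilities

__all__ = [
    "ConditionSpec",
    "SimulationSpec",
    "simulate_cohort",
    "simulate_paired_cells",
    "reference_cohort",
    "type1_power_grid",
]

#: Representative diagnoses used for synthetic gold labels, per lesion type.
_GOLD_POOL = {
    "malignant": ("oral squamous cell carcinoma", "verrucous carcinoma",
                  "mucoepidermoid carcinoma"),
    "benign": ("fibroma", "squamous papilloma", "lipoma"),
    "reactive": ("pyogenic granuloma", "traumatic ulcer", "oral lichen planus",
                 "inflammatory fibrous hyperplasia"),
    "inflammatory": ("oral candidiasis", "mucositis",
                     "chronic nonspecific inflammation"),
}


@dataclass(frozen=True)
class ConditionSpec:
    """Target marginal accuracies for one condition.

    ``accuracies`` is either one accuracy per threshold (applied to every
    stratum) or a mapping stratum-level -> per-threshold accuracies.
    Accuracies must be non-decreasing in the threshold so the generated cube
    satisfies threshold monotonicity.
    """

    condition_id: str
    accuracies: tuple[float, ...] | Mapping[str, tuple[float, ...]]

    def per_stratum(self, levels: Sequence[str], n_thresholds: int) -> dict[str, tuple[float, ...]]:
        if isinstance(self.accuracies, Mapping):
            table = {lvl: tuple(float(p) for p in self.accuracies[lvl]) for lvl in levels}
        else:
            accs = tuple(float(p) for p in self.accuracies)
            table = {lvl: accs for lvl in levels}
        for lvl, accs in table.items():
            if len(accs) != n_thresholds:
                raise SimulationSpecError(
                    f"{self.condition_id}/{lvl}: expected {n_thresholds} accuracies, "
                    f"got {len(accs)}"
                )
            if any(not (0.0 <= p <= 1.0) for p in accs):
                raise SimulationSpecError(
                    f"{self.condition_id}/{lvl}: accuracies must lie in [0, 1]: {accs}"
                )
            if any(a > b for a, b in zip(accs, accs[1:])):
                raise SimulationSpecError(
                    f"{self.condition_id}/{lvl}: accuracies must be non-decreasing "
                    f"in the threshold: {accs}"
                )
        return table


@dataclass(frozen=True)
class SimulationSpec:
    """Full specification of a synthetic cohort.

    ``strata`` maps stratum variable -> {level: proportion}; proportions per
    variable must sum to 1.  ``rho`` is the exchangeable within-case latent
    correlation in [0, 1).  A seed is mandatory: there is no global random
    state anywhere in this package.
    """

    n_cases: int
    conditions: tuple[ConditionSpec, ...]
    seed: int
    rho: float = 0.0
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    strata: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "lesion_type": {"malignant": 0.20, "benign": 0.11,
                            "reactive": 0.35, "inflammatory": 0.34},
            "difficulty": {"low": 0.25, "moderate": 0.40, "high": 0.35},
        }
    )

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise SimulationSpecError("n_cases must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise SimulationSpecError(f"rho must lie in [0, 1), got {self.rho}")
        if not self.conditions:
            raise SimulationSpecError("at least one condition is required")
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise SimulationSpecError(f"duplicate condition ids: {ids}")
        for var, levels in self.strata.items():
            total = sum(levels.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationSpecError(
                    f"stratum proportions for {var!r} sum to {total}, not 1"
                )


def _allocate_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n cases to stratum levels."""
    items = list(proportions.items())
    raw = [n * p for _, p in items]
    counts = [int(np.floor(r)) for r in raw]
    short = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
    for i in order[:short]:
        counts[i] += 1
    return {lvl: c for (lvl, _), c in zip(items, counts)}


def simulate_cohort(spec: SimulationSpec) -> tuple[CorrectnessCube, pd.DataFrame]:
    """Draw one cohort from the latent-threshold model.

    Returns the correctness cube plus a metadata frame (case_id,
    gold_diagnosis, lesion_type, difficulty) indexed like the cube.
    Deterministic for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases
    case_ids = tuple(f"case_{i+1:04d}" for i in range(n))

    # stratum labels, each variable permuted independently
    labels: dict[str, np.ndarray] = {}
    for var, props in spec.strata.items():
        counts = _allocate_counts(n, props)
        col = np.repeat(list(counts.keys()), list(counts.values()))
        labels[var] = col[rng.permutation(n)]
    lesion = labels.get("lesion_type", np.repeat("inflammatory", n))
    difficulty = labels.get("difficulty", np.repeat("moderate", n))

    pools = {lt: _GOLD_POOL.get(lt, ("unspecified lesion",)) for lt in set(lesion)}
    gold = [pools[lt][i % len(pools[lt])] for i, lt in enumerate(lesion)]

    n_thr = len(spec.thresholds)
    z = rng.standard_normal(n)
    values = np.zeros((n, len(spec.conditions), n_thr), dtype=np.uint8)
    for j, cond in enumerate(spec.conditions):
        eps = rng.standard_normal(n)
        t = np.sqrt(spec.rho) * z + np.sqrt(1.0 - spec.rho) * eps
        if isinstance(cond.accuracies, Mapping):
            per = cond.per_stratum(sorted(set(lesion)), n_thr)
            cutoffs = np.array([per[lt] for lt in lesion])  # (n, n_thr)
        else:
            per = cond.per_stratum(["_all"], n_thr)
            cutoffs = np.tile(per["_all"], (n, 1))
        values[:, j, :] = (t[:, None] < stats.norm.ppf(cutoffs)).astype(np.uint8)

    cube = CorrectnessCube(
        values, case_ids, tuple(c.condition_id for c in spec.conditions), spec.thresholds
    )
    metadata = pd.DataFrame(
        {
            "case_id": case_ids,
            "gold_diagnosis": gold,
            "lesion_type": lesion,
            "difficulty": difficulty,
        }
    )
    return cube, metadata


def simulate_paired_cells(
    p_text: float,
    p_img: float,
    n: int,
    reps: int,
    seed: int,
    rho: float = 0.0,
    discordant: tuple[float, float] | None = None,
) -> np.ndarray:
    """Draw matched-pair cell counts (n11, n10, n01, n00) for many replicates.

    Direct multinomial generator with exact discordance control: either
    derive (p10, p01) from the latent-threshold model at correlation ``rho``
    or pass them explicitly.  Used by the power/type-I harness.
    """
    if discordant is not None:
        p10, p01 = float(discordant[0]), float(discordant[1])
    else:
        p10, p01 = discordant_probabilities(p_text, p_img, rho)
    p11 = p_img - p10
    p00 = 1.0 - p11 - p10 - p01
    probs = np.clip([p11, p10, p01, p00], 0.0, 1.0)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("cell probabilities do not sum to 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, probs / probs.sum(), size=reps)


def type1_power_grid(
    cells: Sequence[Mapping[str, float]],
    alpha: float = 0.05,
    reps: int = 2000,
    seed: int = 0,
    exact_cutoff: int = 25,
) -> pd.DataFrame:
    """Empirical rejection rate of auto-mode McNemar over a design grid.

    Each grid cell is a mapping with keys ``n``, ``p_text``, ``p_img`` and
    optionally ``rho`` (default 0).  Returns one row per cell with the
    rejection rate and its Monte-Carlo standard error.  Deterministic for a
    fixed seed (each cell uses an independent child seed).
    """
    if reps < 100:
        raise ValidationError("reps must be >= 100 for a meaningful rate")
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(cells))
    for cell, ss in zip(cells, seeds):
        n = int(cell["n"])
        p_text, p_img = float(cell["p_text"]), float(cell["p_img"])
        rho = float(cell.get("rho", 0.0))
        counts = simulate_paired_cells(
            p_text, p_img, n, reps, seed=int(ss.generate_state(1)[0] % (2**31)), rho=rho
        )
        p_vals = _mcnemar_p_vector(counts[:, 1], counts[:, 2], exact_cutoff)
        rate = float((p_vals < alpha).mean())
        rows.append(
            {
                "n": n, "p_text": p_text, "p_img": p_img, "rho": rho,
                "rejection_rate": rate,
                "mc_se": float(np.sqrt(rate * (1 - rate) / reps)),
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged worked-example cohort
# ---------------------------------------------------------------------------

#: Condition ids of the packaged cohort.  Model A is the vision-synergist
#: (large gain from images), model B the vision-stable model.
REFERENCE_CONDITIONS = (
    "expert", "model_a_image", "model_a_text", "model_b_image", "model_b_text"
)

#: Top-1/3/5 correct counts (out of 200) for each condition.
_REFERENCE_MARGINALS = {
    "expert": (162, 174, 188),
    "model_a_image": (124, 160, 178),
    "model_a_text": (90, 124, 144),
    "model_b_image": (128, 160, 172),
    "model_b_text": (124, 160, 174),
}

_LESION_BLOCKS = (("inflammatory", 68), ("malignant", 40), ("benign", 22), ("reactive", 70))
_DIFFICULTY_SIZES = {"low": 50, "moderate": 80, "high": 70}


def _model_a_joint_categories(n: int = 200) -> np.ndarray:
    """Per-case joint (image, text) category of model A at each threshold.

    Categories are '11', '10', '01', '00' (image, text).  Constrained cells:

    * Top-1 overall: n11=82, b=42, c=8, n00=68; within the 68 inflammatory
      cases (indices 0..67): n11=32, b=18, c=0, n00=18;
    * Top-3 overall: n11=114, b=46, c=10, n00=30;
    * Top-5 overall: n11=138, b=40, c=6, n00=16;

    with the transitions between thresholds chosen as a fixed lexicographic
    arrangement (earliest-index cases upgrade first) that respects monotone
    coupling: a coordinate correct at Top-k never becomes wrong at a larger k.
    """
    cat = np.empty((n, 3), dtype="<U2")
    # Top-1: inflammatory block first (32x'11', 18x'10', 18x'00'),
    # then the remaining 132 cases (50x'11', 24x'10', 8x'01', 50x'00').
    k1 = (["11"] * 32 + ["10"] * 18 + ["00"] * 18
          + ["11"] * 50 + ["10"] * 24 + ["01"] * 8 + ["00"] * 50)
    cat[:, 0] = k1
    # Top-1 -> Top-3: 32 of 42 '10' -> '11'; of the 68 '00': 36 -> '10', 2 -> '01'.
    cur = cat[:, 0].copy()
    _upgrade(cur, "10", "11", 32)
    _upgrade(cur, "00", "10", 36)
    _upgrade(cur, "00", "01", 2)
    cat[:, 1] = cur
    # Top-3 -> Top-5: 6 of '10' -> '11'; 4 of '01' -> '11'; 14 of '00' -> '11'.
    cur = cat[:, 1].copy()
    _upgrade(cur, "10", "11", 6)
    _upgrade(cur, "01", "11", 4)
    _upgrade(cur, "00", "11", 14)
    cat[:, 2] = cur
    return cat


def _upgrade(arr: np.ndarray, src: str, dst: str, count: int) -> None:
    idx = np.flatnonzero(arr == src)[:count]
    if idx.size != count:
        raise AssertionError(f"fixture construction: cannot move {count} {src}->{dst}")
    arr[idx] = dst


def _nested_correct_sets(sizes: Sequence[int], n: int, seed: int) -> np.ndarray:
    """(n, len(sizes)) binary matrix with nested correct sets of given sizes."""
    perm = np.random.default_rng(seed).permutation(n)
    out = np.zeros((n, len(sizes)), dtype=np.uint8)
    for j, size in enumerate(sizes):
        out[perm[:size], j] = 1
    return out


def reference_cohort() -> tuple[CorrectnessCube, pd.DataFrame]:
    """Deterministic 200-case, 5-condition worked-example cohort.

    Marginal Top-1/3/5 counts match the published benchmark for all five
    conditions; model A's image/text paired tables match the reconstructed
    discordant cells at every threshold (Top-1: b=42, c=8; Top-3: b=46,
    c=10; Top-5: b=40, c=6), including the inflammatory-stratum Top-1 table
    (b=18, c=0); lesion strata have sizes 40/22/70/68 and difficulty strata
    50/80/70.  All joint structure beyond these constraints follows a fixed,
    documented canonical arrangement and is NOT the study's real joint data.
    """
    n = 200
    case_ids = tuple(f"case_{i+1:04d}" for i in range(n))

    lesion = np.repeat([lt for lt, _ in _LESION_BLOCKS],
                       [sz for _, sz in _LESION_BLOCKS])
    # difficulty decoupled from lesion blocks by a fixed permutation
    diff_col = np.repeat(list(_DIFFICULTY_SIZES), list(_DIFFICULTY_SIZES.values()))
    difficulty = diff_col[np.random.default_rng(7).permutation(n)]
    gold = [
        _GOLD_POOL[lt][i % len(_GOLD_POOL[lt])] for i, lt in enumerate(lesion)
    ]

    values = np.zeros((n, len(REFERENCE_CONDITIONS), 3), dtype=np.uint8)
    cat = _model_a_joint_categories(n)
    ai = REFERENCE_CONDITIONS.index("model_a_image")
    at = REFERENCE_CONDITIONS.index("model_a_text")
    for m in range(3):
        values[:, ai, m] = np.isin(cat[:, m], ("11", "10")).astype(np.uint8)
        values[:, at, m] = np.isin(cat[:, m], ("11", "01")).astype(np.uint8)
    values[:, REFERENCE_CONDITIONS.index("expert"), :] = _nested_correct_sets(
        _REFERENCE_MARGINALS["expert"], n, seed=11
    )
    values[:, REFERENCE_CONDITIONS.index("model_b_image"), :] = _nested_correct_sets(
        _REFERENCE_MARGINALS["model_b_image"], n, seed=12
    )
    values[:, REFERENCE_CONDITIONS.index("model_b_text"), :] = _nested_correct_sets(
        _REFERENCE_MARGINALS["model_b_text"], n, seed=13
    )

    cube = CorrectnessCube(values, case_ids, REFERENCE_CONDITIONS, DEFAULT_THRESHOLDS)
    metadata = pd.DataFrame(
        {
            "case_id": case_ids,
            "gold_diagnosis": gold,
            "lesion_type": lesion,
            "difficulty": difficulty,
        }
    )
    return cube, metadata
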