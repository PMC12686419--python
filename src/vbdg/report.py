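"""Full analysis battery, overall and within strata.

Assembles, from a correctness cube plus case metadata, the complete set of
study panels:

* per-threshold accuracy with Cochran's Q over the AI conditions and
  Bonferroni-adjusted pairwise McNemar letter groupings;
* the VBDG gain panel per model (absolute / relative gain, error reduction,
  within-model McNemar p, within-model Cohen's h);
* between-model comparisons (difference-of-differences Wald test, log-RR
  delta-method test, and every candidate Cohen's h contrast, explicitly
  labelled);
* the within-case odds-ratio panel, overall and per stratum;
* lesion-type- and difficulty-stratified gain panels.

The battery is a pure function of (cube, metadata, config): repeated runs
produce byte-identical JSON.  Within-stratum p-values are reported raw (no
cross-stratum multiplicity adjustment) by default, matching standard
reporting of stratified paired analyses; a config switch adds Bonferroni
across strata.
"""

from __future__ import annotations

import hashlib
import json
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._version import __version__
from .cohort import CorrectnessCube
from .conditional import conditional_or
from .exceptions import IncompleteMetadataError, ValidationError
from .gain import PairedTable2x2, cohens_h, dod_wald_test, rr_delta_test, vbdg_summary
from .inference import (
    DEFAULT_EXACT_CUTOFF,
    bonferroni,
    cochran_q,
    mcnemar,
    pairwise_groupings,
)

__all__ = ["BatteryConfig", "StudyReport", "stratify", "analysis_battery"]

STRATUM_VARIABLES = ("lesion_type", "difficulty")


def stratify(
    cube: CorrectnessCube, metadata: pd.DataFrame, by: str
) -> dict[str, CorrectnessCube]:
    """Partition a cube into per-level sub-cubes for one stratum variable.

    The partition is disjoint and exhaustive; levels appear in order of
    first appearance in the metadata.  Missing or null labels are an error
    listing the offending cases.
    """
    if by not in metadata.columns:
        raise IncompleteMetadataError(f"metadata has no column {by!r}")
    meta = metadata.set_index("case_id") if "case_id" in metadata.columns else metadata
    missing = [c for c in cube.case_ids if c not in meta.index]
    if missing:
        raise IncompleteMetadataError(f"cases absent from metadata: {missing[:10]}")
    labels = meta.loc[list(cube.case_ids), by]
    null = labels[labels.isna()].index.tolist()
    if null:
        raise IncompleteMetadataError(f"cases with missing {by!r} label: {null[:10]}")
    out: dict[str, CorrectnessCube] = {}
    for level in pd.unique(labels):
        ids = [c for c, lv in zip(cube.case_ids, labels) if lv == level]
        out[str(level)] = cube.subset(ids)
    return out


@dataclass(frozen=True)
class BatteryConfig:
    """Configuration of the analysis battery.

    ``model_pairs`` maps a model label to its (image condition, text
    condition) ids.  ``expert`` names the reference condition shown in
    accuracy tables; by default it is excluded from Cochran's Q (which runs
    over the AI conditions only) but included in the pairwise letter family
    with Bonferroni m = C(q, 2) over all conditions.
    """

    model_pairs: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "model_a": ("model_a_image", "model_a_text"),
            "model_b": ("model_b_image", "model_b_text"),
        }
    )
    expert: str | None = "expert"
    alpha: float = 0.05
    include_expert_in_q: bool = False
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF
    continuity: bool = False
    stratum_variables: tuple[str, ...] = STRATUM_VARIABLES
    adjust_across_strata: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.exact_cutoff < 0:
            raise ValidationError("exact_cutoff must be >= 0")

    def canonical(self) -> dict:
        return {
            "model_pairs": {k: list(v) for k, v in sorted(self.model_pairs.items())},
            "expert": self.expert,
            "alpha": self.alpha,
            "include_expert_in_q": self.include_expert_in_q,
            "exact_cutoff": self.exact_cutoff,
            "continuity": self.continuity,
            "stratum_variables": list(self.stratum_variables),
            "adjust_across_strata": self.adjust_across_strata,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class StudyReport:
    """All panels produced by :func:`analysis_battery`."""

    accuracy: pd.DataFrame
    cochran: pd.DataFrame
    gains: pd.DataFrame
    between_models: pd.DataFrame
    stratified: pd.DataFrame
    or_panel: pd.DataFrame
    provenance: dict

    def to_json(self, indent: int = 2) -> str:
        """Deterministic JSON: full-precision records plus a rendered block."""
        def scalar(v):
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.bool_,)):
                return bool(v)
            if isinstance(v, (float, np.floating)):
                return None if np.isnan(v) else float(v)
            return v

        def records(df: pd.DataFrame) -> list[dict]:
            return [
                {k: scalar(v) for k, v in rec.items()}
                for rec in df.to_dict(orient="records")
            ]

        rendered_gains = [
            {
                "model": r["model"], "k": int(r["k"]),
                "absolute_gain_pp": round(r["absolute_gain_pp"], 1),
                "relative_gain": None if np.isnan(r["relative_gain"]) else round(r["relative_gain"], 2),
                "error_reduction_pct": None if np.isnan(r["error_reduction_pct"]) else round(r["error_reduction_pct"], 1),
            }
            for r in self.gains.to_dict(orient="records")
        ]
        rendered_accuracy = [
            {
                "k": int(r["k"]), "condition": r["condition"],
                "count": int(r["count"]), "n": int(r["n"]),
                "pct": round(100.0 * r["proportion"], 1),
                "letters": r["letters"],
            }
            for r in self.accuracy.to_dict(orient="records")
        ]
        payload = {
            "provenance": self.provenance,
            "accuracy": records(self.accuracy),
            "cochran": records(self.cochran),
            "gains": records(self.gains),
            "between_models": records(self.between_models),
            "stratified": records(self.stratified),
            "or_panel": records(self.or_panel),
            "rendered": {"accuracy": rendered_accuracy, "gains": rendered_gains},
        }
        return json.dumps(payload, indent=indent, sort_keys=False, allow_nan=False)

    def to_markdown(self) -> str:
        """Compact markdown rendering of the headline panels."""
        lines = ["# Study report", ""]
        lines.append("## Accuracy (count (pct) with grouping letters)")
        lines.append("")
        lines.append("| k | condition | correct/n | pct | letters |")
        lines.append("|---|-----------|-----------|-----|---------|")
        for r in self.accuracy.to_dict(orient="records"):
            lines.append(
                f"| {r['k']} | {r['condition']} | {r['count']}/{r['n']} "
                f"| {100 * r['proportion']:.1f}% | {r['letters']} |"
            )
        lines.append("")
        lines.append("## Vision-based diagnostic gain")
        lines.append("")
        lines.append("| model | k | A_text | A_img | abs gain (pp) | rel gain | error reduction |")
        lines.append("|-------|---|--------|-------|---------------|----------|-----------------|")
        for r in self.gains.to_dict(orient="records"):
            rel = "-" if np.isnan(r["relative_gain"]) else f"x{r['relative_gain']:.2f}"
            er = "-" if np.isnan(r["error_reduction_pct"]) else f"{r['error_reduction_pct']:.1f}%"
            lines.append(
                f"| {r['model']} | {r['k']} | {100 * r['a_text']:.1f}% "
                f"| {100 * r['a_img']:.1f}% | {r['absolute_gain_pp']:+.1f} | {rel} | {er} |"
            )
        lines.append("")
        lines.append("## Within-case odds ratios (image vs text)")
        lines.append("")
        lines.append("| scope | model | k | OR | 95% CI | p |")
        lines.append("|-------|-------|---|----|--------|---|")
        for r in self.or_panel.to_dict(orient="records"):
            if r["odds_ratio"] is None or (isinstance(r["odds_ratio"], float) and np.isnan(r["odds_ratio"])):
                lines.append(f"| {r['scope']} | {r['model']} | {r['k']} | - | - | - |")
            else:
                lines.append(
                    f"| {r['scope']} | {r['model']} | {r['k']} | {r['odds_ratio']:.2f} "
                    f"| {r['ci_low']:.2f}-{r['ci_high']:.2f} | {_fmt_p(r['p_value'])} |"
                )
        lines.append("")
        return "\n".join(lines)


def _fmt_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def _ai_conditions(config: BatteryConfig) -> list[str]:
    out: list[str] = []
    for img, text in config.model_pairs.values():
        for cond in (img, text):
            if cond not in out:
                out.append(cond)
    return out


def analysis_battery(
    cube: CorrectnessCube,
    metadata: pd.DataFrame,
    config: BatteryConfig | None = None,
) -> StudyReport:
    """Run the full analysis battery and assemble a :class:`StudyReport`.

    Deterministic: the report depends only on its three arguments.  Cells
    where a statistic is undefined (no discordant pairs; text accuracy 0 or
    1) are flagged in the panel's ``note`` column rather than dropped.
    """
    config = config or BatteryConfig()
    for label, (img, text) in config.model_pairs.items():
        cube.condition_index(img)
        cube.condition_index(text)

    # accuracy + letters + Cochran's Q per threshold ----------------------
    acc_rows, q_rows = [], []
    q_conds = _ai_conditions(config)
    if config.include_expert_in_q and config.expert:
        q_conds = [config.expert] + q_conds
    for k in cube.thresholds:
        grouping = pairwise_groupings(
            cube, list(cube.condition_ids), k=k, alpha=config.alpha,
            exact_cutoff=config.exact_cutoff,
        )
        for cond in cube.condition_ids:
            a = cube.accuracy(cond, k)
            acc_rows.append(
                {"k": k, "condition": cond, "count": a.count, "n": a.n,
                 "proportion": a.proportion, "letters": grouping.letters[cond]}
            )
        idx = [cube.condition_index(c) for c in q_conds]
        mat = cube.values[:, idx, cube.threshold_index(k)]
        q = cochran_q(mat)
        q_rows.append(
            {"k": k, "conditions": "+".join(q_conds), "Q": q.statistic,
             "df": q.df, "p_value": q.p_value, "note": q.notes}
        )

    # per-model VBDG panel ------------------------------------------------
    gain_rows = []
    for label, (img, text) in config.model_pairs.items():
        for k in cube.thresholds:
            table = PairedTable2x2.from_cube(cube, img, text, k)
            res = vbdg_summary(table=table)
            test = mcnemar(table.b, table.c, mode="auto",
                           continuity=config.continuity,
                           exact_cutoff=config.exact_cutoff)
            h = cohens_h(table.a_img, table.a_text)
            gain_rows.append(
                {"model": label, "k": k, "a_text": res.a_text, "a_img": res.a_img,
                 "absolute_gain_pp": res.absolute_gain_pp,
                 "relative_gain": res.relative_gain,
                 "error_reduction_pct": res.error_reduction_pct,
                 "b": table.b, "c": table.c,
                 "mcnemar_p": test.p_value, "mcnemar_method": test.method,
                 "cohens_h_img_vs_text": h.cohens_h, "h_magnitude": h.magnitude,
                 "note": ";".join(sorted(res.undefined_flags))}
            )

    # between-model comparisons ------------------------------------------
    between_rows = []
    labels = list(config.model_pairs)
    for i, m1 in enumerate(labels):
        for m2 in labels[i + 1:]:
            p1, p2 = config.model_pairs[m1], config.model_pairs[m2]
            for k in cube.thresholds:
                t1 = PairedTable2x2.from_cube(cube, *p1, k)
                t2 = PairedTable2x2.from_cube(cube, *p2, k)
                dod = dod_wald_test(cube, p1, p2, k)
                note = dod.notes
                try:
                    rr = rr_delta_test(t1, t2)
                    rr_z, rr_p = rr.statistic, rr.p_value
                except ValidationError as exc:
                    rr_z, rr_p = np.nan, np.nan
                    note = (note + "; " if note else "") + f"rr: {exc}"
                between_rows.append(
                    {"model_1": m1, "model_2": m2, "k": k,
                     "dod_pp": dod.estimate, "dod_z": dod.statistic,
                     "dod_p": dod.p_value, "rr_z": rr_z, "rr_p": rr_p,
                     "h_image_contrast": cohens_h(t1.a_img, t2.a_img).cohens_h,
                     "h_text_contrast": cohens_h(t1.a_text, t2.a_text).cohens_h,
                     "h_within_model_1": cohens_h(t1.a_img, t1.a_text).cohens_h,
                     "h_within_model_2": cohens_h(t2.a_img, t2.a_text).cohens_h,
                     "note": note}
                )

    # stratified panels + OR panel ---------------------------------------
    strat_rows, or_rows = [], []

    def _or_row(scope: str, model: str, k: int, table: PairedTable2x2) -> dict:
        try:
            res = conditional_or(table, alpha=config.alpha,
                                 exact_cutoff=config.exact_cutoff)
            return {"scope": scope, "model": model, "k": k,
                    "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "p_value": res.p_value,
                    "corrected": res.corrected, "b": table.b, "c": table.c,
                    "note": ""}
        except Exception as exc:  # no discordance
            return {"scope": scope, "model": model, "k": k,
                    "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p_value": np.nan, "corrected": False,
                    "b": table.b, "c": table.c, "note": str(exc)}

    for label, (img, text) in config.model_pairs.items():
        for k in cube.thresholds:
            or_rows.append(
                _or_row("overall", label, k, PairedTable2x2.from_cube(cube, img, text, k))
            )

    for var in config.stratum_variables:
        sub = stratify(cube, metadata, var)
        if sum(s.n_cases for s in sub.values()) != cube.n_cases:
            raise ValidationError(f"strata for {var!r} do not partition the cohort")
        n_levels = len(sub)
        for level, subcube in sub.items():
            scope = f"{var}:{level}"
            for label, (img, text) in config.model_pairs.items():
                other = [m for m in labels if m != label]
                for k in cube.thresholds:
                    table = PairedTable2x2.from_cube(subcube, img, text, k)
                    test = mcnemar(table.b, table.c, mode="auto",
                                   continuity=config.continuity,
                                   exact_cutoff=config.exact_cutoff)
                    p = test.p_value
                    if config.adjust_across_strata:
                        p = float(bonferroni([p], m=n_levels)[0])
                    row = {
                        "variable": var, "level": level, "n": subcube.n_cases,
                        "model": label, "k": k,
                        "a_text": table.a_text, "a_img": table.a_img,
                        "gain_pp": (table.a_img - table.a_text) * 100.0,
                        "b": table.b, "c": table.c,
                        "mcnemar_p": p, "mcnemar_method": test.method,
                        "h_within_model": cohens_h(table.a_img, table.a_text).cohens_h,
                        "note": test.notes,
                    }
                    if other:
                        o_img, o_text = config.model_pairs[other[0]]
                        o_table = PairedTable2x2.from_cube(subcube, o_img, o_text, k)
                        row["h_image_contrast_vs_" + other[0]] = cohens_h(
                            table.a_img, o_table.a_img
                        ).cohens_h
                        row["h_text_contrast_vs_" + other[0]] = cohens_h(
                            table.a_text, o_table.a_text
                        ).cohens_h
                    strat_rows.append(row)
                    or_rows.append(_or_row(scope, label, k, table))

    provenance = {
        "package": "vbdg",
        "version": __version__,
        "config": config.canonical(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_cases": cube.n_cases,
        "conditions": list(cube.condition_ids),
        "thresholds": list(cube.thresholds),
    }
    return StudyReport(
        accuracy=pd.DataFrame(acc_rows),
        cochran=pd.DataFrame(q_rows),
        gains=pd.DataFrame(gain_rows),
        between_models=pd.DataFrame(between_rows),
        stratified=pd.DataFrame(strat_rows),
        or_panel=pd.DataFrame(or_rows),
        provenance=provenance,
    )
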