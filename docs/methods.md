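# Methods

## Study design the package models

A paired (case-matched) diagnostic-accuracy design: every case in a cohort
is assessed by every condition, where a condition is a rater or an AI model
under a fixed input modality.  Each assessment is a ranked list of at most
five candidate diagnoses; correctness at rank threshold k (Top-1, Top-3,
Top-5 by default) is binary.  Because all conditions see the same cases,
every contrast is within-case, and the whole inference stack is built on
matched-pair and matched-set statistics rather than independent-proportion
ones.

The central object is the correctness cube, a binary array indexed
(case, condition, threshold) with a hard invariant: correctness is monotone
non-decreasing in the threshold within each (case, condition).  Incomplete
designs (missing case × condition cells) are rejected, never imputed — each
paired test assumes complete matched data, and silent imputation would bias
the discordant counts that carry all the information.

## Scoring and adjudication

Correctness is adjudicated by exact matching of normalized labels
(lowercase, punctuation stripped, whitespace collapsed), optionally routed
through a user-supplied synonym map that is applied to both the candidate
and the gold label and resolved to a fixed point.  Human adjudication of
near-synonyms is irreproducible; externalizing it as an explicit map keeps
the scoring deterministic and auditable.  Pre-adjudicated binary
correctness can be loaded directly, bypassing matching entirely.  Fuzzy or
semantic matching is deliberately out of scope.

## The VBDG metrics

For a model with text-only accuracy `A_text` and text+image accuracy
`A_img` on the same cases:

* absolute gain (pp): `(A_img − A_text) × 100`;
* relative gain: `A_img / A_text`, undefined (flagged, NaN) at `A_text = 0`;
* error reduction (%): `100 (E_text − E_img) / E_text`, `E = 1 − A`,
  undefined (flagged) at `A_text = 1` — it is reported as undefined, never
  as 0 or ∞.

The identity `abs = 100 · A_text · (rel − 1)` and the sign equivalence
`abs > 0 ⇔ rel > 1 ⇔ ER > 0` (for `A_text ∈ (0,1)`) are property-tested.
Rendering follows clinical-table conventions — one decimal for percentage
points and percentages, two for ratios — with full precision kept
internally and rounding applied only at render time.

## Test conventions

**McNemar.** Exact two-sided p is the doubled upper tail
`min(1, 2·P(X ≥ max(b,c)))`, `X ~ Binomial(b+c, ½)`; for this symmetric
distribution the doubled tail coincides with the minimum-likelihood
two-sided tail, so the choice is innocuous but stated.  The asymptotic
statistic is `(|b−c| − cc)² / (b+c)` with the continuity correction off by
default (`cc = 0`): this is what makes Cochran's Q at k = 2 collapse
exactly to the McNemar chi-square, an equivalence the tests verify on 1,000
random matrices.  Auto mode switches to the exact test when `b + c ≤ 25`.
`b + c = 0` is degenerate: p = 1 with a flag, since concordant pairs carry
no information about marginal homogeneity.

**Cochran's Q** uses the standard column/row-sum form with df = k − 1;
all-constant rows contribute nothing, and an all-constant matrix is
degenerate (Q = 0, p = 1, flagged).

**Pairwise letters.** All C(q,2) pairwise McNemar tests, Bonferroni family
m = C(q,2), then a Piepho-style insert-and-absorb compact letter display
ordered by descending accuracy.  The letters reproduce the significance
relation exactly (shared letter ⇔ adjusted p ≥ α), verified by
reconstruction.  By default the expert condition is included in the letter
family but excluded from Cochran's Q, which runs over the AI conditions
only; both choices are configurable because reporting practice varies.

**Within-case odds ratios.** `OR = b/c` on the discordant cells equals the
conditional-logistic MLE for a within-case binary exposure (the conditional
likelihood is `b ~ Bin(b+c, e^β/(1+e^β))`); the tests confirm this against
a numerical likelihood maximization.  When `b = 0` or `c = 0`, the
Haldane–Anscombe correction adds 0.5 to *both* discordant cells (only
then), which keeps the estimate and the log-scale Wald variance
`1/b + 1/c` finite.  Alternatives (correcting all four cells, or always
correcting) change reported values for zero-cell strata and were rejected.
P-values always use the uncorrected counts: the correction serves
estimation, not testing.

The Wald interval uses the conventional two-decimal normal critical value
(1.96 at α = 0.05) by default, matching how such tables are conventionally
computed and reported; `exact_z=True` switches to the full-precision
quantile (1.959964…), which narrows the interval by a fraction of a percent.

**Between-model gain tests.** The paper-style "difference of differences"
is tested per case: `d_i = (x^A_img,i − x^A_text,i) − (x^B_img,i −
x^B_text,i)`, `z = mean(d) / (sd(d)/√n)` with the sample (n−1) standard
deviation.  Using the per-case d vector respects the within-case
correlation across all four conditions; an independent-proportions variance
would be mis-calibrated in either direction depending on the correlation
structure.  A seeded case-resampling bootstrap is provided as a
cross-check.  The log-risk-ratio comparison uses the matched-pair
delta-method variance `Var(ln RR) = (b+c)/((n11+b)(n11+c))` per model and
treats the two models' log RRs as independent — the minimal assumption when
only marginal tables are available; the bootstrap captures the shared-case
covariance when the cube is available.

**Effect sizes.** Cohen's `h = 2 arcsin√p₁ − 2 arcsin√p₂` with the usual
benchmarks (|h| < 0.2 trivial, < 0.5 small, < 0.8 medium, else large).
Stratified panels report *all* candidate h contrasts explicitly labelled
(within-model image-vs-text, between-model image, between-model text)
rather than a single unlabelled value, because stratified tables in the
literature are often ambiguous about which contrast they standardize.

**Multiplicity.** Bonferroni only (`p_adj = min(1, m·p)`).  Within-stratum
p-values are reported raw by default — matching how stratified paired
analyses are conventionally reported — with an opt-in Bonferroni across
strata.

## Power and sample size

For discordant probabilities `(p10, p01)` with `ψ = p10 + p01` and
`δ = p10 − p01`, the closed-form (Connor-type) approximation is

    power = Φ( (|δ|√n − z_{1−α/2}√ψ) / √(ψ − δ²) ).

At a 20-point effect (60% vs 80%) under independence (`p10 = 0.32`,
`p01 = 0.12`, α = 0.05) the smallest n reaching 80% power is 84, consistent
with a minimum-80-case design under mild positive within-case correlation
(positive dependence shrinks ψ at fixed δ and raises power, a trend the
simulation harness verifies over ρ ∈ {0, 0.3, 0.6}).  Monte-Carlo power
draws the four paired cells from a multinomial per replicate and applies
auto-mode McNemar, so it reflects the exact-test switch at small
discordance.

## The simulator

Latent-threshold Gaussian copula: case i draws a shared `z_i ~ N(0,1)`;
condition c draws `t_ic = √ρ·z_i + √(1−ρ)·ε_ic` and is correct at
threshold k iff `t_ic < Φ⁻¹(p_ck)`.  Marginals are exact in expectation;
ρ ∈ [0,1) gives exchangeable within-case dependence across any number of
conditions; sharing `t_ic` across thresholds yields monotone coupling, so
every generated cube satisfies the threshold-monotonicity invariant by
construction.  Per-stratum target accuracies are supported for the
lesion-type variable.  A direct multinomial paired-cell generator provides
exact discordance control for the power harness.  Seeds are mandatory;
nothing uses global random state.

What the simulator does *not* emulate: diagnosis text (it emits correctness
bits, with representative gold labels only for round-tripping the readers),
rater learning or ordering effects, non-exchangeable dependence between
specific condition pairs, and any association between strata and
correctness unless explicitly specified.  Passing tests therefore validate
the statistical machinery under a known data-generating process, not the
clinical claims of any particular study.

Useful closed form: at latent correlation r and a common threshold, two
conditions disagree with probability `arccos(r)/π` — e.g. 1.42% at
r = 0.999 — which is how the comonotone-limit test calibrates its bound.

## The packaged worked-example cohort

`reference_cohort()` returns a deterministic 200-case, 5-condition,
3-threshold cube.  Constrained features (these, and only these, are
benchmark-faithful):

* marginal correct counts per condition and threshold — expert
  162/174/188, model A image 124/160/178, model A text 90/124/144, model B
  image 128/160/172, model B text 124/160/174 (of 200);
* model A's image/text paired tables: Top-1 (n11=82, b=42, c=8, n00=68),
  Top-3 (114, 46, 10, 30), Top-5 (138, 40, 6, 16);
* the inflammatory-stratum model-A Top-1 table (n11=32, b=18, c=0, n00=18)
  on its 68 cases;
* stratum sizes 40/22/70/68 (lesion type) and 50/80/70 (difficulty).

Where two published accuracy figures conflicted for the same cell, the
cohort anchors on the assignment jointly consistent with the printed gain,
ratio, error-reduction and effect-size values (model A image Top-1 62.0%,
not 64.0%; the Top-5 image/text assignment consistent with ER 60.7% and
−7.7%).  All joint structure beyond the constraints above — expert × model
dependence, model B's pairing, threshold transitions — is a fixed
lexicographic arrangement (earliest-index cases upgrade first, fixed
permutations for the nested correct sets) chosen for determinism and
auditability.  It is synthetic and must not be read as the source study's
joint data; in particular Cochran's Q values computed on it are canonical
to this arrangement.

## Numerical and degenerate-input policy

* Zero-variance difference vectors: z = 0 / p = 1 when the mean is also
  zero (flagged degenerate), signed infinite z with p reported as 0 and a
  note otherwise.
* `b + c = 0`: McNemar degenerate (p = 1); conditional OR raises a
  no-discordance error (undefined, not 1).
* Fleiss' κ with a single category everywhere: NaN (undefined), and exact
  1.0 at perfect agreement.
* Accuracies/p-values validated into [0,1]; thresholds strictly increasing
  positive integers; enum labels closed (lesion type, difficulty).
* Table reconstruction from printed marginals requires an exact integer
  solution (tolerance 1e-6) and reports the failing constraint otherwise;
  equal accuracies with a target OR ≠ 1 are correctly diagnosed as
  infeasible, and OR = 1 with equal accuracies is reported as unidentified.

## Problem sizes used in the checked examples

The property and calibration tests run at sizes chosen to make Monte-Carlo
error negligible relative to the asserted bounds: exhaustive enumeration for
exact-test agreement (all b+c ≤ 25), 1,000 random matrices for the Q/McNemar
equivalence, n = 50,000 cohorts for marginal recovery and the ρ = 0
independence check (3–4 binomial SEs), 10,000 replicates for the type-I and
power calibration at n = 200 and n = 84.  All are vectorized and complete in
seconds.

## Known limitations

* Exact-matching adjudication is stricter than expert adjudication; without
  a synonym map, accuracies on free-text differentials are lower bounds.
* The delta-method RR comparison ignores between-model covariance (use the
  bootstrap when per-case data are available).
* No mid-p exact variants, no Holm/FDR alternatives, no weighted κ, no
  covariate-adjusted conditional logistic regression — the discordant-pair
  reduction covers the supported designs.
* The simulator's dependence is single-parameter exchangeable; it cannot
  represent, e.g., two models being more correlated with each other than
  with the expert.
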