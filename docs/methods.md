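# Methods

This note documents the models, formulas, defaults and numerical choices
behind `emrqi`, and what the synthetic validation does and does not
establish.

## The index system and its weights

The packaged default system is a depth-3 tree: 4 dimensions → 11
sub-dimensions → 33 leaf indicators. Weights are stored as *absolute*
(global-scale) fractions printed to 3 decimals; relative weights are always
derived as `absolute / parent_absolute` rather than stored, so there is one
source of truth and serialization round-trips exactly.

Printed 3-decimal weights do not conserve exactly: two sibling groups sum
one unit of the third decimal above their parent (temporal-integrity
children 0.032 + 0.031 vs 0.062; compliance children sum 0.090 vs 0.089),
and the Correctness children sum to 0.265 vs 0.264. Weight validation
therefore accepts per-parent residuals up to a default tolerance of 0.002,
and the global sum of the 33 leaf weights is 1.003, not 1.000. A dataset
with every indicator at 1.0 consequently totals 1.003; roll-ups are
leaf-driven, so additivity (total = Σ weighted leaves) holds to 1e-9 while
agreement with the printed dimension weights holds only to the rounding
tolerance.

### Delphi statistics

* Response rates: positive coefficient = responded/invited,
  effective rate = valid/responded (both reported in percent).
* Authority: Cr = (Cs + Ca)/2, acceptable at ≥ 0.7. Cs is the mean mapped
  familiarity score; Ca is the mean over experts of summed per-basis
  influence scores. The *default* mapping tables are the standard Delphi
  conventions (familiarity 1.0/0.8/0.6/0.4/0.2; judgment rows
  0.5/0.4/0.3, 0.3/0.2/0.1, 0.1/0.1/0.1, 0.1/0.1/0.1). The packaged
  16-expert study panel instead ships with a **synthetic calibrated**
  familiarity mapping (0.97 / 0.81): the published consultation reports
  the panel composition (7 very familiar, 9 relatively familiar) and the
  coefficients Cs = 0.88, Ca = 0.90, but not its own mapping tables, and
  no mapping on the conventional 0.2 grid can produce 0.88 from 16
  experts. The calibrated mapping reproduces both coefficients exactly and
  is clearly labelled as a reconstruction, not a reproduction.
* Per-indicator CV uses the sample (n−1) standard deviation — panels are
  small — over the mean, missing ratings dropped pairwise; CV ≥ 0.25 is
  flagged. A zero mean or a single rating is reported as undefined, never
  silently dropped.
* Kendall's W uses average ranks within each expert and the standard tie
  correction W = [ΣR_j² − m²n(n+1)²/4] / [m²(n³−n)/12 − mΣT_i/12];
  experts with any missing rating are excluded listwise. Significance uses
  χ² = m(n−1)W with n−1 df. If every expert rates all items identically
  the denominator vanishes and W is reported as 0 (no discriminating
  information). W > 0.2 is flagged acceptable.

### AHP

Judgment matrices are built from sibling mean ratings, a_ij = m_i/m_j —
exactly consistent by construction (CR = 0). An optional snap-to-Saaty mode
rounds off-diagonal ratios to the reciprocal 1–9 scale, introducing the
realistic inconsistency the CR test exists for; it is off by default since
the plain ratio is the documented construction. The principal eigenvector
comes from power iteration (tolerance 1e-10, max 1000 iterations; positive
reciprocal matrices are primitive so convergence is guaranteed), with the
row-geometric-mean estimator exposed as a cross-check; both agree to 1e-8
on consistent matrices. CI = (λ_max − n)/(n − 1), CR = CI/RI with the
Saaty RI table for orders 1–15 (0 for n ≤ 2, so 1×1 and 2×2 matrices pass
by convention). Weight derivation fails closed if any group's CR ≥ 0.1.
Level-3 sibling groups use the percentage rule (mean rating / group sum)
rather than AHP, matching the documented construction of the system; for
unsnapped ratio matrices the two coincide.

The published weights cannot be re-derived exactly because the underlying
expert ratings are unpublished; the derivation path is validated by
round-trip (weights → proportional means → weights) and by a synthetic
panel experiment (below).

## Indicator formulas

The published construction defers the 33 exact leaf formulas to
supplementary material that is not in the main text, so the formulas here
are this package's own definitions, kept deliberately simple and
registry-pluggable (`emrqi.indicators.CALCULATORS`) so alternative
formulations can be dropped in without touching the engine or the scoring
roll-up. All are ratios (conforming units / measured units) or bounded
quantities; highlights and edge policies:

* Missing cells are NaN/None, empty strings, or configured sentinel codes
  (default "", "-1", "9999", "NA", "N/A"). Timestamps parse as ISO 8601 by
  default (schema-overridable); unparseable values count as invalid, never
  as errors.
* Element resolution is by case-insensitive name/synonym match against the
  schema. Ambiguity (one dataset column resolving to several concepts) is
  scored by the unambiguity indicator over *resolvable* elements;
  unmapped elements are a mapping problem and are scored there instead.
* Sample adequacy is min(1, n / required n). Balance indicators use the
  Shannon entropy of the observed category distribution normalized by
  log k (k observed categories; k = 1 scores 0), clamped to [0, 1].
* Granularity: a numeric column meets its declared precision if the median
  count of significant decimals (trailing zeros ignored, measured on the
  string form) reaches the requirement; the score is the fraction of
  requirement-bearing columns that meet it.
* Temporal order: a record complies when its anchors parse, admission ≤
  discharge, every *parseable* measurement time lies within the stay, and
  nothing postdates the extraction date. Missing measurement timestamps do
  not violate order — they are scored by timestamp integrity — keeping the
  defect axes orthogonal.
* Timeliness: fraction of values with recording delay in [0, τ], τ = 24 h
  by default. Frequency: per monitored element and record,
  min(1, observed/expected) with expected = ceil(stay/interval), at least
  1; averaged over elements then records.
* Method unambiguity and method consistency share one computation (a
  tagged element has exactly one distinct method tag): on a single
  dataset, "one tag" and "constant across records" are the same predicate.
  They remain separate registry entries because pluggable replacements
  (e.g. cross-source method comparison) would differ.
* Not-evaluable results (no schema support, nothing to measure, zero
  denominators) score 1.0 with a prominent warning by default — the
  benefit-of-the-doubt reading appropriate when cohorts from a single
  source are compared and such indicators are constant. Alternatives:
  score 0.0, or exclude with sibling-weight renormalization.

## Association analysis

Pearson's r is computed from the defining sum form; Spearman's ρ from
1 − 6Σd²/(n(n²−1)) in the tie-free case and Pearson on average ranks with
ties. The normality gate runs Shapiro–Wilk on both series and picks
Pearson only if both pass at α = 0.05 (conservative both-must-pass
reading). Right-tailed p-values use t = r√((n−2)/(1−r²)) with n−2 df for
both methods; an exact permutation p is available for n ≤ 8. Constant
series yield an explicitly undefined (NaN) coefficient, never a
significant flag.

The packaged reproduction fixtures are the printed first-level scores and
model-performance tables of the five published ICU cohorts. That path
bypasses the gate and uses Pearson throughout: at n = 5 Shapiro–Wilk has
essentially no power, and Pearson on the printed 3-decimal values
reproduces all nine published coefficients within ±0.005, flagging eight
of nine significant (all but LR-precision).

The optional modeling harness follows the published protocol: median
imputation, undersampling of the majority class to 1:1, seeded stratified
80/20 split, standardization fitted on training data, optional ten-fold CV
on the training side, and held-out accuracy/precision/AUC for LR
(liblinear), SVM (RBF, C = 1.0, gamma = scale) and RF (10 trees, depth 7,
sqrt features — the modern spelling of the historical "auto"). SVM AUC
uses the signed decision margin, which is ranking-equivalent to a
probability.

## Synthetic cohorts

`generate_cohort` draws a clean ICU-style cohort: demographics, four labs
(log-normal), a derived BMI element, admission/discharge anchors (stays
log-normal around 60 h, clipped to 12–500 h; cadence and anchors agree
because the effective stay is taken from the stored minute-floored
timestamps), three vitals every 4 h with units and method tags, and a
binary sepsis-like outcome from a logistic model on five standardized
predictors (coefficients 0.8/0.9/1.1/0.7/0.6; intercept solved by root
finding to hit the requested prevalence, default 0.25 — a realistic
high-risk ICU screening rate; balanced 0.5 is used where a "flawless"
dataset is required, since an imbalanced outcome genuinely is a quality
deficit under the balance indicator). Effect sizes give a clean held-out
AUC ≈ 0.80–0.85, leaving headroom for defect-driven degradation.

Defects are per-opportunity Bernoulli events injected in a fixed order
(dropout → thinning → missingness → missing timestamps → delays → range →
format → unit → derived corruption → state flags → label noise), so rates
compose predictably; realized counts are reported in the ground truth and
are recountable from the emitted tables, never forced exact. Range
violations apply to *every* plausibility-checked value (demographics,
labs, vitals), so the range-conformance score recovers 1 − rate directly.
With a fixed seed the generator is byte-deterministic, and because defect
masks at different rates share the same uniform draws they are nested:
raising a rate can only add defects, making score monotonicity exact
per-seed rather than merely statistical.

Label noise is deliberately outside the indicator set: with a balanced
outcome it leaves every score unchanged while collapsing model AUC — the
documented scope boundary of a data-quality index (with an imbalanced
outcome, symmetric flips shift the class marginal toward 0.5 and the
output-balance indicator does move).

What a green synthetic suite does **not** establish: clinical realism
(no disease progression, no realistic lab correlation structure), the
published real-data performance numbers (credentialed access), or the
published Kendall's W values (reported only as bounds, and the authors'
tie treatment is unknown).

## Expert-panel generator

Ratings are clip(round(latent + ε), 1, 5) with ε ~ N(0, 1/consensus);
consensus ≤ 0 degenerates to uniform random ratings and consensus = ∞ to
the rounded latents. Rounding to the Likert grid is dithered by the noise,
so panel mean ratings are nearly unbiased for the latents at moderate
consensus (≈ 3); the weight-recovery experiment (latents proportional to
the four dimension weights, 60 experts) re-derives the dimension weights
within 0.02 with ample margin.
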