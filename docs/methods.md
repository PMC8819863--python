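# Methods

## Outcome and model family

The outcome is binary amyloid-PET positivity (global florbetapir SUVR >
1.11).  Candidate predictors are four plasma biomarkers — the Aβ42/40
ratio (code A; IP-MS or Simoa assay, chosen per analysis), GFAP (G),
NfL (N) and p-tau181 (P) — on a demographic base of age, sex and APOE-ε4
carriership.  When cognitively unimpaired (CU) and impaired (CI)
participants are pooled, a CU/CI indicator joins the base; within-stratum
analyses omit it.  All 2⁴ biomarker subsets (including the demographic-only
model) are fitted by maximum-likelihood logistic regression
(Newton/IRLS, tolerance 1e−8 on the log-likelihood, 100 iterations max).

Preprocessing: right-skewed concentrations (GFAP, p-tau181, NfL) are
log-transformed; the Aβ ratios and age enter linearly; all continuous
predictors are mean-centred (centering leaves likelihoods, information
criteria and fitted probabilities unchanged — it only conditions the
optimisation — and this invariance is tested).  Binary predictors are 0/1
indicators (female, APOE carrier, CI).

Per fit we record logL, k (all coefficients including the intercept),
AIC = 2k − 2logL, BIC = k·ln n − 2logL, the in-sample AUC of the fitted
probabilities with a DeLong 95% CI, and four pseudo-R² variants (McFadden,
adjusted McFadden, Cox–Snell, Nagelkerke).  No variant is privileged: the
published summary table does not identify which R² it reports, and none of
the four reproduces its printed percentages from the printed likelihood
arithmetic, so they are reported side by side and never asserted.
Similarly, the LRT column is computed against both plausible references —
the intercept-only null (whose closed-form likelihood reproduces the
published χ² values for the pooled-sample rows) and the demographic model —
and labelled.

Quasi-separation is detected (runaway standardized coefficients, or an
essentially perfect in-sample likelihood) and flagged rather than raised;
flagged fits are excluded from model selection and counted in robustness
reports.  A Firth-type penalized fallback was considered and deliberately
not enabled: at the study's n the flags are rare and excluding them is
transparent, whereas silently switching estimators mid-family would make
AIC/BIC values non-comparable.

## The selection decision tree

1. Best-fitting model = lowest AIC (ties: fewer parameters, then
   lexicographic name).
2. Candidates = models within `aic_window` = 2 AIC units of it.
3. Each candidate nested with the best model (either direction) is
   LR-tested against it; the candidate is excluded when the test is
   significant at α = 0.05 *and* the candidate is the inferior (subset)
   member of the pair.  Non-nested candidates cannot be LR-tested; they
   are retained and flagged in the audit trail.
4. Selected = lowest BIC among the best model and surviving candidates
   (same tie rule).

The result object carries the complete audit trail (candidate ΔAICs, LRT
exclusions with χ² and p, the BIC ranking) and serializes to JSON.  The
α used inside the tree is the study-wide 0.05; no multiplicity correction
is applied across candidates, matching the procedure being modelled.

Note one arithmetic consequence tested as an invariant: for nested fits on
the same rows, χ² = (AIC_small − AIC_large) + 2·df, so a subset candidate
within 2 AIC units of the best model can only be excluded when
χ² ∈ (3.84, 2 + 2·df]; with df = 1 the exclusion window is narrow, which is
why the tree usually resolves at the BIC step.

## Synthetic cohort generator

The generator reproduces the study sample from its printed summary
statistics; it exists so the pipeline is fully testable without
access-restricted data.

* **Composition** (defaults): 58 Aβ− / 60 Aβ+; CU/CI 30/28 and 20/40;
  female 41.4% / 43.3% and APOE-ε4 25.9% / 53.3%, drawn as exact counts
  (rounded rate × group size) so printed contingency tables reproduce
  exactly (`exact_counts=False` switches to Bernoulli draws).
* **Marginals**: every biomarker and the SUVR are log-normal per amyloid
  group, quartile-matched to the printed median (IQR):
  μ = ln median, σ = ln(q75/q25)/(2·z₀.₇₅), z₀.₇₅ ≈ 0.6745.  This matches
  the median and the quartile *ratio* exactly; when a printed IQR is
  asymmetric on the log scale (notably p-tau181 in the Aβ+ group) the
  individual endpoints are matched only approximately — the unavoidable
  cost of a two-parameter family.  Age, education and MMSE use normal
  approximations from median/IQR (MMSE truncated to [0, 30] and rounded).
* **Dependence**: a Gaussian copula couples the five assay columns within
  each group.  The true inter-marker correlations are not published;
  defaults are an assumption — +0.4 among GFAP/p-tau181/NfL, −0.25 between
  those and each Aβ ratio, +0.6 between the two Aβ assays — validated as
  positive-definite and fully configurable.  Diagnosis, sex and APOE are
  independent of the markers *within* an amyloid group; real data would
  show residual within-group associations (e.g. MMSE with p-tau181).
* **SUVR consistency**: SUVR is drawn from the group log-normal truncated
  to the correct side of the 1.11 threshold, so group sizes are exact and
  no post-hoc relabeling occurs.

What passing tests on this generator do show: the estimator and
decision-tree machinery are correct against closed-form oracles, and the
robustness mechanism (noise variance eroding small log-scale group
separation) behaves quantitatively as predicted.  What they do not show:
agreement with the restricted participant-level data — in-sample AUCs and
which specific model wins at n = 118 depend on the unpublished joint
distribution, and draw-to-draw selection variability at that sample size is
substantial (the analysis scripts make this visible rather than hiding it).

## Noise model

Perturbation multiplies each assay value by (1+u), u supported on
[−c, +c] with c the simulated CV: uniform by default (the variability being
simulated is "within and up to" a bound), or a truncated normal
(sd = c/2, bounds ±2 sd) for sensitivity.  The Aβ42/40 ratio is perturbed
as a single value, never numerator and denominator separately.  Only
biomarker columns are touched.  Randomness derives from
SeedSequence(base seed, CV-level index, iteration index), so any level or
iteration is reproducible in isolation.

For log-normal marginals the population AUC under noise is
Φ(|Δμ|/√(σ₋² + σ₊² + 2·Var[ln(1+U)])), with the log-noise moments obtained
by quadrature (for uniform noise, Var[ln(1+U)] ≈ c²/3 to within 2% at
c ≤ 0.2).  This oracle predicts the study's central contrast: the IP-MS
Aβ42/40 ratio (Δμ ≈ 0.079, pooled σ ≈ 0.094) falls from AUC 0.80 to 0.66
at c = 0.20, while GFAP (Δμ ≈ 0.372, pooled σ ≈ 0.64) falls by less than
0.01 — and the empirical curves are tested against it.  The single-marker
crossover sits between c = 0.10 and 0.15, so selection-shift assertions are
placed at c ≥ 0.15.

## Statistical inference components

* **AUC**: Mann–Whitney pair statistic with the ½ tie convention, computed
  via midranks in O(n log n); an O(n_pos·n_neg) brute-force count is kept
  as a test oracle and the two agree exactly on 1,000 random instances.
* **DeLong variance / paired test**: per-participant placement components;
  variance S₁₀/m + S₀₁/n; paired comparisons use the component covariance.
  Frozen reference values on a fixed 12-participant instance agree with an
  independent implementation to 10 decimals, and CI widths / p-values agree
  with stratified-bootstrap oracles within ±0.02.
* **Group comparisons**: Welch t (Student and Mann–Whitney behind flags)
  for continuous variables summarized as median (IQR); Pearson χ² for
  contingency tables.  Yates continuity correction is per-call: the
  published table's own 2×2 p-values are consistent only if correction
  usage varied between rows (uncorrected reproduces the diagnosis-split
  p = 0.04, corrected the sex p = 0.98), so no single convention is
  hard-coded; the default is uncorrected.

## Problem sizes and defaults

Study-scale analyses use the printed n = 118.  Convergence-to-oracle
checks use 10⁴–10⁵ participants per group, where the Monte-Carlo error of
an AUC is below 0.005; robustness iteration counts default to 10, the
study's stated repeat count (also used for the single-biomarker curves,
where the study does not state one; mean and min–max band are reported).
All randomness flows from explicit integer seeds; identical configuration
and seed reproduce every table byte-for-byte.

## Known limitations

* Marginals are exactly log-normal by construction; heavier-tailed or
  contaminated real-world assay distributions would change absolute AUCs,
  though not the noise-variance mechanism.
* The copula is an assumption; sensitivity to it can be explored through
  `GeneratorConfig.copula_correlation` but no published target exists.
* In-sample AUCs are reported (as in the procedure being modelled); no
  cross-validation, so AUCs of selected models are optimistic.
* The CU/CI indicator enters pooled models as a covariate with no
  biomarker interaction; stage-dependent biomarker effects are only
  captured by fitting the strata separately.
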