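# Methods

## Problem setting

A cohort of prostate-cancer patients undergoes radical prostatectomy;
some later show biochemical recurrence (return of detectable serum PSA).
Per patient we have routine clinico-pathological variables and, from
organotypic slice cultures of the resected tumour, qPCR expression of a
panel of MALAT1-responsive transcripts (MALAT1, ME3, PDK3, PDK1, CHKA,
pS2, PSA) before and after MALAT1 knockdown with an antisense gapmer
(LacZ gapmer as control). The question is whether molecular features
improve recurrence classification over the clinical picture alone.

## Composite clinical variables

* **Pathological stage code**: pT2a→1, pT2b→2, pT2c→3, pT3a→4, pT3b→5.
  Stage strings are tokenised; a leading "T" is normalised to "pT"; N/M
  tokens are ignored. A string without a sub-stage letter (e.g. "T2 Nx
  Mx") is *unknown*, not an error — such rows are later removed by
  listwise deletion rather than guessed.
* **ISUP grade group** from Gleason primary+secondary using the standard
  grade-group table (3+3→1, 3+4→2, 4+3→3, sum 8→4, sum 9–10→5). The
  source material names only "ISUP grading"; the 2014 grade-group table is
  the accepted mapping and its group summaries are consistent with it.
* **Adverse-clinical-features score**: weighted sum 1·LVI + 2·margins +
  3·ECE + 0.5·PNI over the *positive* flags, range 0–6.5. Flags are
  ternary (true/false/unknown); one unknown flag makes the whole score
  unknown, because a lower bound would silently understate tumour burden.

## Feature sets and missing data

classical = {age, serum PSA, ISUP, stage code, adverse score};
new = classical ∪ basal fold changes of the 7 transcripts;
new_bis = new ∪ modulation ratios (silenced/basal) of ME3, PDK3, PDK1, PSA.

Missing values are handled by listwise deletion at matrix-assembly time,
with the dropped patient ids reported. No imputation is attempted: at
n ≈ 40 with p up to 16, imputation noise would be material and the
workflow this mirrors likewise dropped an incomplete sample. A matrix
with fewer than two complete rows in either class is an error.

Design choices deliberately left configurable: MALAT1 basal expression is
included in the molecular criteria (its component loading is informative),
age stays in every criterium as part of the classical superset, and the
binary adverse flags enter only through the weighted score (keeping them
as standalone columns too would double-count; they remain available for
univariate Fisher tests).

## qPCR quantities

Fold change uses the comparative-Ct convention 2^−ΔΔCt with perfect
amplification efficiency; "fold change vs control = 1" then holds by
construction. Silencing efficiency is (1 − fold change)·100 %, negative
when expression rose. The efficient-silencing filter keeps patients with
depletion ≥ 17 % (inclusive, matching a sample counted at exactly 17 %).
Mitochondrial DNA content is 2^(Ct_RPLP0 − Ct_ND1), the two-gene ΔCt
form; a standard-curve method would need calibrator data that the assay
layout does not provide.

## Assay calculators

Lactate: concentration = ((OD − OD_blank)·dilution − intercept)/slope.
The printed source formula has unbalanced parentheses; this reading is
the standard inversion of a linear calibration (subtract blank, scale by
dilution, invert the curve). The calculator is unit-agnostic — the
standard curve's concentration unit is authoritative. Enzyme activity
follows Beer–Lambert: rate = (dA/dt)/(ε·ℓ), scaled by reaction volume and
normalised per 10⁶ cells; ε defaults are the tabulated millimolar
coefficients 6.3×10⁻³ (NADH, 340 nm) and 12.42×10⁻³ (DCIP, 600 nm),
stored as constants and not silently unit-corrected.

## PLS-DA

* **Scaling**: unit-variance autoscaling (mean 0, sample sd 1, ddof = 1),
  the chemometric default; zero-variance columns are dropped with a
  warning. Scaling is always estimated on training folds only.
* **Y coding**: recurrent = 1, non-recurrent = 0, mean-centred.
* **NIPALS**: per component w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt,
  q = yᵀt/tᵀt, deflate X ← X − tpᵀ. With a univariate response the inner
  loop converges in one pass; it is retained (tolerance 1e-10 on the
  weight change, ≤ 500 iterations) to keep the algorithm general.
  Y-deflation is omitted — equivalent for a single response.
* **Sign convention**: the weight entry of largest magnitude is made
  positive, so loadings and scores are reproducible across runs and
  platforms.
* **Explained X-variance** per component: ‖t pᵀ‖²_F / ‖X_scaled‖²_F.
* **Prediction**: ŷ = ȳ + X_scaled·B with B = W(PᵀW)⁻¹q. A row at the
  training centroid predicts exactly ȳ.

Degenerate inputs: a single-class y is an error; if deflation exhausts X
before the requested number of components, fitting stops early with a
warning; a feature matrix with no variation at all cannot produce a
component and the caller (cross-validation) falls back to the mean
predictor.

## Evaluation

* **Q2**: leave-one-out; PRESS = Σ(yᵢ − ŷ₋ᵢ)², TSS = Σ(yᵢ − ȳ)² with ȳ
  the full-sample mean; Q2(A) = 1 − PRESS/TSS, and the component count
  maximising Q2 is selected. Leave-one-out (rather than k-fold, which is
  available through the same interface by refitting) is the natural
  choice at n ≈ 16–40. A useful closed-form check: with featureless X the
  LOO predictor is the fold mean (nȳ − yᵢ)/(n−1) and Q2 = 1 − (n/(n−1))²
  exactly.
* **Permutation p**: labels are shuffled B times (default 1000) and the
  *entire* selection-plus-LOO procedure is re-run per permutation, so the
  null statistic is exchangeable with the observed one; p = (b+1)/(B+1),
  giving a floor of 1/(B+1) ≈ 0.001 at B = 1000.
* **AUC**: Mann–Whitney pair statistic via midranks (ties count ½),
  invariant under monotone score transforms.
* **AUC CI**: stratified bootstrap (resampling within class, so every
  replicate keeps both classes), percentile interval, clipped to [0, 1].
  Default B = 2000.
* **Youden threshold**: candidates are midpoints between adjacent
  distinct scores plus ±∞; prediction rule "score ≥ threshold ⇒
  recurrent"; ties in J broken toward the smallest maximising threshold
  (the most sensitive of the equivalent rules).
* **Fisher exact test**: two-sided hypergeometric (point-probability
  criterion), delegated to scipy; an exhaustive-enumeration oracle checks
  it in the tests.

## Synthetic cohort generator

The generator emulates the study conditions: 28 non-recurrent / 12
recurrent patients; group summaries ISUP 2.25 ± 0.80 vs 3.1 ± 0.70, stage
code 2.86 ± 0.71 vs 3.92 ± 0.90, adverse score 1.00 ± 1.18 vs 2.83 ±
1.67, ECE positivity 25 % vs 75 %, SVI 0 % vs 33 %.

* Ordinals (ISUP, stage) are drawn by rounding a latent normal and
  clipping to 1..5. Rounding-plus-clipping biases the mean, so the latent
  mean is solved by root-finding so the *discretised* expectation equals
  the target exactly; the configured sd is used as the latent sd.
* Adverse flags are independent Bernoullis. The ECE probability is
  pinned to its configured rate; the common probability of the remaining
  three flags is solved from the target score mean given the weights. An
  unreachable mean raises an infeasibility error instead of clipping.
  The configured score *sd*s are treated as descriptive; with Bernoulli
  flags the variance is implied and not separately matched.
* SVI is identified with stage pT3b (staging semantics). The generator
  compares the configured SVI rate with the rate implied by the stage
  distribution and warns if they disagree by more than 0.10; the stage
  draw wins.
* Expression is log2-normal (multiplicative qPCR noise): basal log2 fold
  change ~ N(effect·class, sd), default sd 1.0 per gene. Default basal
  effects (+0.8 for MALAT1, ME3, PDK3, CHKA; −0.6 for pS2; 0 for PDK1 and
  PSA) follow the reported signs of the component correlations; the
  magnitudes are free, moderate choices, not published values. Silenced
  MALAT1 = basal × (1 − depletion/100) with depletion ~ N(12 %, 25 %)
  truncated at 99 %, chosen so roughly 40 % of patients pass the 17 %
  filter, matching the observed 17-of-40 funnel. Other genes' silenced
  values apply a mild average repression (−0.3 log2) plus an optional
  class shift of the modulation ratio.
* Age ~ round N(66.5, 6.2) clipped to 45–90 and serum PSA ~ logN(2.05,
  0.45) reproduce the ranges of the printed clinical table.
* Clinical and molecular variables are independent given the class; the
  real within-group covariance is unknown and not emulated. Consequently,
  passing tests demonstrate the *machinery* (calibration, error control,
  recovery of injected signal), not clinical performance on real data.
* The null generator equalises all group parameters and zeroes all
  effects, so labels are independent of features — used for calibration
  tests of the permutation p-value, Q2 and Fisher test.

All randomness flows from one integer seed through numpy's PCG64
generator; identical parameters give byte-identical cohorts.

## Problem sizes in the tests

Test problem sizes were chosen as the smallest that make each property
statistically decisive: permutation calibration uses 200 null cohorts of
n = 20 with B = 99 permutations (3σ binomial band around 0.05); generator
calibration uses 10,000 patients per group (Monte-Carlo s.e. well below
the 0.05 tolerance); signal recovery uses 50 seeds of 40-patient cohorts
with strong injected effects (log2 effect 2.0, sd 0.7) and B = 199
(p-floor 0.005 ≤ the 0.01 criterion).

## Known limitations

* Headline metrics of the motivating study (Q2 0.40/0.33/0.42, AUC
  0.96/0.93, errors 10 %/18 %/0 %) depend on unavailable patient
  expression data; they serve as calibration anchors for the synthetic
  defaults, not as reproduction targets.
* Which 10 of the 50 enrolled patients were excluded to form the n = 40
  analysis set is not identifiable from the printed table, so the exact
  28/12 split cannot be reconstructed from the fixture.
* The printed table contains one internally inconsistent row (patient 37:
  no recurrence but a 5-month recurrence time); it is preserved verbatim
  and flagged with a warning on load.
* No survival modelling of time-to-recurrence, no multi-class PLS-DA, no
  amplification-efficiency (Pfaffl) correction, no imputation.
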