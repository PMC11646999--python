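# Methods

## The problem and the quantities computed

Patients with advanced non-small-cell lung cancer on immune checkpoint
inhibitors either achieve durable clinical benefit — progression-free for at
least six months from therapy start (DCB) — or progress early (NDB).
The package predicts that binary outcome from blood drawn before treatment
and at an early on-treatment timepoint (median ≈ 26 days), plus the first
imaging assessment, through three kinds of quantities:

1. **ctDNA concentration.** A plasma sample with detected somatic variants
   carries `maxVAF × cfDNA[pg/mL] / 3.3` haploid genome equivalents of tumor
   DNA per mL (one haploid genome ≈ 3.3 pg). A sample with no detected
   variants has concentration 0 and is flagged undetectable.
2. **Dynamics.** ΔctDNA is the on-treatment concentration over baseline.
   An undetectable *baseline* is replaced by the cohort limit of detection
   (LOD) before dividing; an undetectable *on-treatment* sample counts as 0;
   both undetectable gives Δ = 0 in a distinct `persistently_negative`
   category. Molecular response is Δ ≤ 0.2 (≥ 80 % drop, boundary
   inclusive); "decreased" means Δ strictly below 1.
3. **Burden features.** bTMB is the nonsynonymous variant count per megabase
   of a 1.5-Mb panel; normalized bTMB divides bTMB by the *baseline* ctDNA
   concentration (it is a pre-treatment feature, so the on-treatment sample
   never enters it).

The classifier is an ordinary binary logistic regression over
log₁₀ normalized bTMB, log₁₀ ΔctDNA, and the 0/1 coding of CR/PR at the
first RECIST assessment.

## Conventions and numerical choices

- **LOD policy.** The default LOD is the minimum positive baseline
  concentration observed in the cohort; an explicit
  `MetricsConfig.lod_hge_per_ml` overrides it. The LOD must be positive;
  normalized bTMB for a ctDNA-negative baseline uses the same substitution.
- **Persistently negative patients** count as molecular responders by
  default (`MetricsConfig.negative_is_responder`); they are kept in a
  separate dynamics category so reports can split them out.
- **DCB labeling.** Time ≥ 6 months ⇒ DCB regardless of later progression;
  progression or death before 6 months ⇒ NDB; censored before 6 months ⇒
  `indeterminate`, excluded from classification (mirroring the exclusion of
  patients with insufficient follow-up).
- **Kaplan–Meier median**: earliest time with Ŝ(t) ≤ 0.5, `None` when the
  curve never reaches 0.5. KM estimation itself is delegated to lifelines.
- **Log-rank** is computed in-package from the risk table (observed − expected
  with the hypergeometric variance), because the cutpoint scan needs it once
  per candidate split; it agrees with lifelines to 1e-9 in the tests.
- **Cox PH** is fitted in-package by Newton maximization of the partial
  likelihood with step halving (monotone log-likelihood), Efron ties by
  default (Breslow available), convergence at gradient max-norm < 1e-8 or
  100 iterations. Wald CIs from the observed information. Monotone
  likelihood (separation) leaves a flagged, warned, unconverged result.
  The partial log-likelihood is exposed (`cox_partial_loglik`) so optima can
  be audited by finite differences; lifelines is the cross-check in tests.
- **Maximally selected cutpoint.** Candidates are the distinct observed
  biomarker values, split as low ≤ c < high; splits leaving either side
  below `minprop` (default 10 %) of subjects are inadmissible; the winner
  maximizes |standardized log-rank z|, ties to the smallest cutpoint. The
  adjusted p-value of the maximally selected statistic is deliberately not
  computed — downstream use needs the cutpoint, not its significance.
- **Logistic fitting** is IRLS with step halving on the (optionally ridge-
  penalized) deviance, tolerance 1e-8, 100 iterations. Coefficients whose
  magnitude exceeds 30 on the model scale signal complete separation; the
  fit is then automatically repeated with ridge 1e-6 and a warning.
- **Feature transform.** ΔctDNA and normalized bTMB span orders of magnitude
  and contain exact zeros, so both enter as `log10(max(x, 1e-4))`. The floor
  1e-4 sits well below any observable positive ratio in cohorts of this size
  and maps persistently negative patients to −4.
- **Operating point.** ROC thresholds are ±∞ plus midpoints between
  consecutive sorted unique scores; a patient is predicted DCB when score
  strictly exceeds the threshold. Youden's J ties break toward higher
  specificity, then higher threshold — early identification of NDB patients
  is the clinically costly call, so specificity wins ties.
- **Cross-validation** is stratified 5-fold repeated 20 times, all fold
  assignments derived from one seed. **External validation** freezes
  transforms, standardization statistics, coefficients and threshold.

## The synthetic cohort generator

Real patient-level data for this problem are access-restricted, so the
generator is a first-class module that emulates the cohort's statistical
structure. Its defaults *are* the study conditions:

| parameter | default | meaning |
|---|---|---|
| `dcb_prevalence` | 0.675 | P(latent DCB) |
| `delta_bin_probs_dcb` | (0.839, 0.054, 0.107) | P(Δ bin) for DCB over (0, 0.2], (0.2, 1), [1, ∞) |
| `delta_bin_probs_ndb` | (0.296, 0.074, 0.630) | same for NDB |
| `persistently_negative_prob_dcb/ndb` | 0.05 / 0.0 | ctDNA never detected |
| `recist_probs_dcb` | (0.415, 0.585, 0.0) | P(PR, SD, PD) at first scan |
| `recist_probs_ndb` | (0.136, 0.546, 0.318) | NDB PD rate from 7 PD among 22 evaluable NDB |
| `pfs_median_dcb/ndb` | 13.6 / 4.2 months | class-conditional KM medians |
| `dcb_window` | 6 months | benefit rule |
| `censor_prob` | 0.3 | administrative censoring among DCB |

Generation is hierarchical and conditionally independent given the latent
class (the two molecular features were observed to be independent in the
source cohort): class → (PFS, RECIST, ΔctDNA bin, bTMB) independently, then
variant tables consistent with the drawn ΔctDNA.

Specific modeling choices:

- **PFS.** DCB times are `6 + Exponential` with median 13.6 − 6 = 7.6
  months, so the class and the 6-month rule are consistent by construction.
  Censoring uses an *independent* competing time `6 + Exponential(rate_c)`
  with `rate_c = λ·p/(1−p)`: the memoryless race censors exactly a fraction
  `p = censor_prob` in expectation while keeping the KM estimator of the
  event distribution consistent (dependent censoring schemes — e.g. a
  censoring time drawn uniformly below the event time — bias the KM median
  upward by over a month at these parameters). NDB times are an exponential
  truncated to (0, 6) whose conditional median is 4.2 months; since a
  decaying exponential truncated to (0, 6) always has median < 3, the solved
  rate is negative (density increasing toward the window) — the bisection
  searches signed rates.
- **ΔctDNA.** With probability `persistently_negative_prob` the patient is
  ctDNA-negative at both timepoints (Δ = 0); otherwise a bin is drawn from
  the class's 3-vector and Δ is log-uniform within the bin. The bin bounds
  are (1e-3, 0.2, 1, 10): the response and increase cut-points are fixed by
  the definitions above, while the outer bounds are unobserved and
  configurable; log-uniform reflects that these ratios are naturally
  log-scaled.
- **Variant emission.** Baseline variant count ~ Poisson(4) truncated ≥ 1,
  baseline maxVAF log-normal per class (DCB centred lower: less circulating
  tumor burden), cfDNA log-normal (median 10 ng/mL) at both timepoints. The
  on-treatment maxVAF is set so the *recomputed* concentration ratio equals
  the drawn Δ exactly; other VAFs scale proportionally. When that would
  demand VAF > 0.5 the on-treatment cfDNA is redrawn up to 10 times (keeping
  the largest draw), then clipped at 0.5 with the patient flagged
  (`vaf_clipped`, ~1.5 % of default cohorts, concentrated in the NDB
  increased bin) — so the exact round-trip property holds for every
  unclipped patient and clipped patients keep a smaller-than-drawn Δ.
- **Sampling day** is log-normal with median 26 days, floored at 14.
- bTMB is log-normal with DCB median 8 and NDB median 4 mutations/Mb
  (log-sd 0.8): the classes must differ with DCB higher, and these levels
  straddle the conventional high-bTMB region; the exact values are
  otherwise free parameters of the simulation, not estimates.

**What the generator does *not* emulate:** sequencing noise and depth,
panel composition, clonal structure and tumor evolution, correlated
features beyond the latent class, informative censoring, multi-site
heterogeneity, or the leukocyte transcriptome. Calibration tests passing on
synthetic cohorts therefore establish that the *pipeline* recovers the
rates and survival distributions it was pointed at — not that the
classifier would achieve any particular accuracy on new clinical data.

## Problem sizes used in the checks

Calibration checks run at 20,000 simulated patients, where each
class-conditional rate is tested against a 3-standard-error binomial band
and each KM median against a 3-σ delta-method band derived from the
generating law. Oracle-equivalence checks (AUC vs pairwise concordance,
Youden vs exhaustive scan, cutpoint vs exhaustive log-rank scan at n ≤ 50,
logistic/Cox gradients at the optimum) run on 20–200 random datasets each.
Null calibration uses 2,000 log-rank replicates at n = 80 and a 500-patient
null-feature CV; parameter recovery uses n = 2,000 (Cox HR 2.0) and
n = 5,000 (logistic coefficients within 3 SEs). These sizes make every
Monte-Carlo band tight enough to be informative while keeping the whole
suite to a few minutes on one core.

## Known limitations

- The LOD used by the original study is unpublished; the cohort-minimum
  policy is a reasonable stand-in but changes ΔctDNA for baseline-negative,
  on-treatment-positive patients.
- The generator's DCB molecular-response expectation is
  `0.05 + 0.95 × 0.839 ≈ 84.7 %`, slightly above the printed 83.9 %,
  because persistently negative patients also count as responders; the two
  published counts for the 0.5-fold and 0.2-fold thresholds are not
  mutually consistent, and the generator targets the 0.2-fold (response)
  figure.
- Cox fitting supports neither time-varying covariates nor stratification;
  the maximally selected statistic is reported without its adjusted
  p-value.
- The classifier accepts continuous or dichotomized features, but the
  default is continuous; published operating characteristics may refer to
  either coding.
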