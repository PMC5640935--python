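# Methods

## Study design being modelled

The pipeline re-creates a nested case-control study of organ-specific
first metastasis in a hospital breast-cancer cohort. Patients enter at
histological diagnosis, are followed until death/censoring, and their
distant recurrences are recorded per organ site with times in days since
diagnosis. Three case populations are defined from the first events per
organ category: bone-only, visceral-only, and metasynchronous
bone-and-visceral spread.

### Pattern classification

Sites map to two categories: *bone* = {bone, bone marrow, spinal cord
compression, pathological fracture, hypercalcaemia}; *visceral* = {lung,
liver, brain, ascites}; everything else is ignored. With `t_b`/`t_v` the
earliest category times, a timeline is `bone_and_visceral` iff both exist
and `|t_b − t_v| ≤ w`, single-site iff only one exists or the other lags
by more than `w`, and `none` otherwise.

Choices made where the design was open:

* the "6-month" window is fixed at **w = 183 days**, boundary inclusive
  (a gap of exactly 183 days is metasynchronous) and configurable;
* simultaneous bone and visceral events (gap 0) are metasynchronous;
* ignored sites never influence the label — distant sites outside the two
  categories (e.g. skin) are treated as uninformative;
* the window is anchored at the first bone/visceral event, not at the
  first distant event of any kind.

### Risk-set sampling

At each case's event day *T* (calendar scale: diagnosis date + `t_first`),
the risk set contains every patient with `diagnosis_date ≤ T`,
`exit_date > T` and no metastasis event on or before *T* (half-open
convention: an event or exit exactly on *T* removes the candidate).
Controls are drawn uniformly **without replacement within a set, with
replacement across sets**; a patient may serve as control repeatedly and
may later become a case. 1:m sets (default m = 3) are reduced to 1:1
pairs by a uniform draw. Deficits (risk set smaller than m) and unmatched
cases are flagged, never silently dropped.

## Synthetic cohort generator

The generator is the test harness: it produces data with exactly the
structure the analysis assumes, so estimator validity can be checked
against known truth.

* **Calendar frame** — diagnosis days uniform on a 30-year accrual window
  (day 0–10 957), administrative horizon day 14 610, exponential drop-out
  with mean 15 years; median follow-up lands near a decade.
* **Covariates** — ER status Bernoulli(0.68); latent module scores
  `s_j ~ N(0, 1)`, independent unless a correlation matrix is supplied.
* **Events** — cause-specific exponential hazards
  `λ_site = λ0_site · exp(Σ_k β_site,k z_k)`; first-bone and
  first-visceral times are drawn independently, then the later site's
  residual waiting time is redrawn with its hazard multiplied by the
  coupling factor **ρ** (by memorylessness this equals a piecewise-
  constant coupled-hazard model). ρ > 1 induces metasynchronicity and
  directly controls the bone-and-visceral fraction. Constant (exponential)
  baselines were chosen so closed-form survival checks are available.
* **Expression** — member gene g of module j has
  `x_g = direction_g · τ_j · s_j + ε`, `ε ~ N(0, σ²)` (defaults τ = 1,
  σ = 1); overlapping modules accumulate contributions; all other genes
  are pure noise. Generation is at gene level; an optional probe expansion
  duplicates genes into 1–3 probes of increasing noise to exercise
  most-variable-probe resolution.
* **Defaults** (λ0_bone = 3.9×10⁻⁵/day, λ0_visc = 5.8×10⁻⁵/day, ρ = 25)
  were calibrated once to the motivating cohort's printed regime — about a
  third of patients metastasizing, visceral-first roughly twice as common
  as bone-first, and about a quarter of metastasizers metasynchronous —
  and produce ~33 % / split ~28 : 45 : 27 across seeds.
* The default module panel carries one proliferation-like module with a
  per-unit hazard ratio of 2 on both sites (the magnitude regime of the
  matched-set analyses) and one null module for calibration.

What the generator does **not** emulate: treatment-covariate confounding,
competing mortality, non-proportional or time-varying hazards, copy-number
or subtype-specific genomic structure, probe-level QC artefacts, and
batch effects. Passing tests therefore demonstrate correctness of the
*machinery* under the stated generative assumptions, not robustness of
the scientific conclusions to real-data violations of them.

All randomness flows through one seeded generator per run; cohorts are
bit-reproducible. The ground-truth record (latent scores, uncensored
times, true coefficients) is emitted for tests only — a pipeline run with
the truth slot poisoned produces identical output, and a test asserts
this.

## Scoring

* **Weighted sums** — `score_s = Σ_g w_g x_{g,s}`, weights ±1; missing
  genes are skipped and counted, an all-missing module is an error.
* **Series scaling** — within each case-control series, scores are mapped
  affinely `x → (x − c)/h` with `c`/`h` the midpoint/half-width of the
  series' central 95 % interval (linear-interpolation quantiles, the
  type-7 dialect — stated because quantile conventions shift `h`). The
  default reference is the whole series (cases + controls); a
  controls-only reference is available. Scaling is order-preserving, so
  every rank statistic of the scores is unchanged; it is applied before
  regression so per-unit odds ratios are comparable across modules.
* **Centroid subtyping** — genes median-centred across samples, then each
  sample assigned the centroid with maximal Spearman correlation; the
  correlation step is invariant to strictly increasing transforms of the
  sample values. Centroid values are user-supplied; none ship with the
  package.
* **NanoString chain** — per sample: background `b = mean(neg) + 2·sd(neg)`
  subtracted with flooring at 0; counts rescaled so each sample's
  housekeeping geometric mean equals the grand mean; `log2(count + 1)`
  (the +1 offset admits zero counts after background subtraction); and
  per-sample centring by the mean log2 endogenous value, which is the
  log-domain equivalent of dividing by the sample geometric mean (stated
  explicitly to avoid double transformation). Samples with zero
  housekeeping geometric mean are excluded with a flag. Module scores on
  these data standardise each gene (mean 0, SD 1) across the ER-positive
  stratum before the weighted sum; zero-SD genes are dropped.
* **Probe resolution** — a gene measured by several probes keeps the probe
  with maximal sample SD computed on the dataset being scored; SD ties
  break to the lexicographically smallest probe id and are logged.

## Inference

* **Unconditional logistic regression** — IRLS with intercept;
  convergence when the maximal absolute score component < 1e-8 (primary)
  or the relative log-likelihood change stagnates below 1e-14; SEs from
  the inverse observed information. The tight stagnation guard (rather
  than a looser log-likelihood tolerance) is what makes the 1:1
  conditional fit and the paired-difference fit agree to 1e-10.
* **Conditional logistic regression** — Newton–Raphson on the exact
  conditional likelihood for one-case strata of any size; strata without
  covariate variation are counted uninformative and contribute nothing;
  all-uninformative input is rejected. For 1:1 strata the model equals an
  intercept-free logistic fit on within-pair differences (asserted to
  1e-10 in tests against the IRLS path).
* **Separation** — coefficients exceeding |β| > 15 on SD-standardised
  covariates flag complete/quasi-complete separation; the fit is marked
  non-converged and non-reportable instead of diverging silently. Maximum
  50 Newton/IRLS iterations.
* **Wald inference** — OR = exp(β̂), CI = exp(β̂ ± z·SE); profile
  likelihood is not used, matching standard epidemiological output.
* **Rank tests** — Mann-Whitney uses midranks; p is exact by enumeration
  (subset-sum dynamic programming) when n₁+n₂ ≤ 12 without ties,
  otherwise a tie-corrected normal approximation with 0.5 continuity
  correction; two-sided p doubles the smaller tail, capped at 1. Wilcoxon
  signed-rank drops zeros, is exact for n ≤ 25 without ties (sign-flip
  enumeration), with the same approximation rules otherwise. Degenerate
  inputs (all tied, all zero) return p = 1 with a flag.
* **BH-FDR** — step-up `p̃_(i) = min_{j≥i} m·p_(j)/j` capped at 1; applied
  across the module panel within each series × model-family block.
* **ROC/AUC** — rank formula with ties counted ½, so `AUC·n₁·n₀` equals
  the Mann-Whitney U of the positive class identically, including ties.
* **Quartile analysis** — thresholds are the control series' 25/50/75th
  percentiles; both pair members are binned, exposure is coded Q2–Q4
  against Q1, and a conditional fit is run; a quartile with no discordant
  pair is reported non-estimable rather than fitted.

## Signature discovery

Pairs are filtered to those whose case **and** control share the requested
ER stratum (unknown status drops the pair). The reference group defaults
to controls of those pairs with no distant event during their entire
follow-up ("never metastasizing"); an all-ER-matched-controls option
exists because the narrower reading is not the only defensible one. The
per-gene comparison is an **unpaired** two-sided Mann-Whitney test —
deliberately so, even though the data arise from pairs, matching the
design's explicit test choice — vectorised across genes with the
identical midrank/tie-correction arithmetic as the scalar test (asserted
in tests). Genes at BH-adjusted p < 0.2 enter the module with the sign of
the case-minus-reference median difference (mean as tie-break); an empty
selection is a legal, flagged outcome. ROC evaluation on the derivation
samples is labelled resubstitution (optimistically biased); no
cross-validation is run by default because the modelled design did not
cross-validate.

## Validation experiments and problem sizes

The acceptance suite runs at sizes chosen to keep the full suite under a
minute while leaving Monte-Carlo error well inside the asserted bands:

* **Estimator validity** — 200 replicates of: cohort n = 2000 with one
  module at true hazard ratio 2 per unit score on both sites, a 100-pair
  BV series, and a conditional fit on the latent score. This experiment
  sets ρ = 2000 so the second site follows the first almost surely within
  the window: at moderate ρ the metasynchronous label itself selects on
  the score through the second event's hazard `exp(βs)`, and the
  case-control contrast then estimates more than the first-event hazard
  ratio (measured mean β̂ ≈ 1.27 at ρ = 25 versus log 2 ≈ 0.693). With
  near-deterministic coupling the label is score-independent and the
  estimator is unbiased (measured bias ≈ 0.01, CI coverage ≈ 0.95).
* **Oracle equivalence** — conditional β̂ against a ±0.005 grid search of
  the conditional likelihood (20 instances), paired-difference
  equivalence to 1e-10, and the exact U–AUC identity on tied data.
* **Calibration** — Mann-Whitney type-I error at n = 30/30 over 10⁴ null
  replicates; mean false-discovery proportion of FDR-0.2 selection over
  200 simulations with 21 planted genes among 2000.
* **Signature recovery** — 100 runs with 21 planted genes (19 up, 2 down)
  at a one-SD effect among 5000 genes, n = 50/50, with held-out AUC on an
  independent draw. Note an arithmetic consequence of the FDR level: with
  ~20 true discoveries selected at q = 0.2, the expected false-positive
  count is about `q/(1−q)·TP ≈ 5` and approximately Poisson, so roughly
  four runs in ten exceed 5 false positives even though the procedure
  controls FDR exactly as intended; the recovery rate and held-out AUC
  are the robust summaries.

## Known limitations

* Exponential baselines make hazard ratios and odds ratios from
  incidence-density sampling coincide cleanly; real cohorts with strongly
  time-varying hazards would need the classifier and sampler unchanged
  but a more careful interpretation of the OR.
* Matching is on event calendar time only; no countermatching or
  covariate matching.
* The discovery stage's reference-group definition and the ER-stratum
  pooling are configurable precisely because the modelled design leaves
  them ambiguous; defaults are documented above.
* Exact rank-test enumeration thresholds (12 / 25) trade speed for
  exactness at the sizes where the normal approximation is weakest; they
  are fixed constants, not tuned values.
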